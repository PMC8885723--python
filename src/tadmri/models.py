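"""Voxel-level signal models as scikit-learn style estimators.

Each estimator wraps one nonlinear (or log-linear) least-squares model of a
single voxel's signal decay:

* :class:`GammaDecayModel` — stretched-exponential decay versus gradient
  strength at constant diffusion time (pseudo-superdiffusion exponent
  gamma, sensitive to susceptibility-induced field inhomogeneity),
* :class:`AlphaDecayModel` — stretched-exponential decay versus diffusion
  time at constant gradient strength (transient subdiffusion exponent
  alpha),
* :class:`QSpaceBiexponentialModel` — low-q two-compartment Gaussian model
  returning the extracellular fraction and the intra/extracellular
  displacement widths,
* :class:`LorentzianPropagatorModel` — Lorentzian fit of the displacement
  profile obtained by Fourier transforming the mirrored q-space signal,
* :class:`DiffusionTensorModel` — log-linear single-shell tensor fit,
* :class:`RelaxometryModel` — mono-exponential T2/T2* decay.

All estimators follow the scikit-learn contract: hyperparameters in
``__init__``, data in ``fit(X, y)``, fitted attributes with a trailing
underscore, and deterministic output (no random restarts).  Nonlinear
problems are solved with SciPy's trust-region reflective bounded
least-squares (tolerance 1e-10, at most 400 iterations by default);
parameters pinned at a bound are reported through ``at_bound_``.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.optimize import least_squares
from sklearn.base import BaseEstimator

__all__ = [
    "GammaDecayModel",
    "AlphaDecayModel",
    "QSpaceBiexponentialModel",
    "LorentzianPropagatorModel",
    "DiffusionTensorModel",
    "RelaxometryModel",
    "propagator_from_signal",
]


def _column(X):
    X = np.asarray(X, dtype=float)
    if X.ndim == 2 and X.shape[1] == 1:
        X = X[:, 0]
    if X.ndim != 1:
        raise ValueError("X must be a 1D array or a single-column 2D array")
    return X


def _invalid_result(est, attrs):
    for name, value in attrs.items():
        setattr(est, name, value)
    est.converged_ = False
    est.valid_ = False
    est.residual_norm_ = np.nan
    return est


class GammaDecayModel(BaseEstimator):
    """Stretched-exponential fit of signal attenuation versus q.

    Model (normalized attenuation, q in rad/mm, Delta in ms)::

        S(q) = p1 * exp((-p2 * q^p3 - D0 * q0^2) * Delta) + p4

    with the noise-floor offset ``p4`` fixed (0.15 by default, matching the
    value the four-parameter pilot fits converge to on magnitude data) and
    the pseudo-superdiffusion exponent gamma = p3 / 2 in [0, 1].  Since the
    amplitude p1 is free, the baseline-attenuation correction term
    exp(-D0 q0^2 Delta) is a constant factor absorbed by p1; it changes the
    reported amplitude, never gamma.

    Internally q is converted to rad/m and Delta to seconds so that the
    conventional initialization (p1, p2, p3) = (1, 1e-10, 1.8) applies, and
    p2 is optimized on a log scale (it spans many decades between the
    initialization and the optimum).

    Parameters
    ----------
    Delta : float
        Diffusion time, ms.
    p4 : float
        Fixed noise-floor offset in normalized signal units.
    d0 : float
        Baseline diffusivity for the q0 correction, mm^2/s (0 disables).
    q0 : float or None
        Reference q in rad/mm; defaults to the smallest q in the data.

    Attributes
    ----------
    amplitude_ : float      fitted p1
    dgen_ : float           generalized diffusion constant p2 (SI: q in rad/m, t in s)
    p3_ : float             stretching exponent, in [0, 2]
    gamma_ : float          p3_ / 2
    residual_norm_ : float  Euclidean norm of residuals
    converged_ : bool
    at_bound_ : bool        p3 pinned at a box bound
    valid_ : bool           False when the voxel could not be fitted
    """

    def __init__(self, Delta=40.0, p4=0.15, d0=0.0, q0=None,
                 init=(1.0, 1e-10, 1.8), lower=(0.0, 0.0, 0.0),
                 upper=(np.inf, np.inf, 2.0), tol=1e-10, max_iter=400):
        self.Delta = Delta
        self.p4 = p4
        self.d0 = d0
        self.q0 = q0
        self.init = init
        self.lower = lower
        self.upper = upper
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        q = _column(X) * 1e3          # rad/mm -> rad/m
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(q) & np.isfinite(y)
        if np.unique(q[ok]).size < 5:
            return _invalid_result(self, dict(
                amplitude_=np.nan, dgen_=np.nan, p3_=np.nan, gamma_=np.nan,
                at_bound_=False))
        q, y = q[ok], y[ok]
        dt = self.Delta * 1e-3        # s
        q0 = (self.q0 * 1e3) if self.q0 is not None else q.min()
        d0_si = self.d0 * 1e-6        # mm^2/s -> m^2/s
        base = d0_si * q0**2
        p4 = self.p4

        # log-p2 box: wide enough for any physical generalized diffusion
        # constant, tight enough that trf's bound-based scaling stays sane
        lo = [self.lower[0], math.log(max(self.lower[1], 1e-28)), self.lower[2]]
        hi = [self.upper[0],
              math.log(self.upper[1]) if np.isfinite(self.upper[1]) else 11.0,
              self.upper[2]]

        def residual(p):
            p1, logp2, p3 = p
            return p1 * np.exp((-np.exp(logp2) * q**p3 - base) * dt) + p4 - y

        x0 = [self.init[0], math.log(self.init[1]), self.init[2]]
        res = least_squares(residual, x0, bounds=(lo, hi), method="trf",
                            xtol=self.tol, ftol=self.tol, gtol=self.tol,
                            max_nfev=self.max_iter * 10)
        p1, logp2, p3 = res.x
        self.amplitude_ = float(p1)
        self.dgen_ = float(math.exp(logp2))
        self.p3_ = float(p3)
        self.gamma_ = float(p3 / 2.0)
        self.residual_norm_ = float(np.linalg.norm(res.fun))
        self.converged_ = bool(res.status > 0)
        self.at_bound_ = bool(
            abs(p3 - self.lower[2]) < 1e-4 or abs(p3 - self.upper[2]) < 1e-4
        )
        self.valid_ = True
        self._q0_si = float(q0)
        return self

    def predict(self, X):
        q = _column(X) * 1e3
        dt = self.Delta * 1e-3
        base = self.d0 * 1e-6 * self._q0_si**2
        return (self.amplitude_
                * np.exp((-self.dgen_ * q**self.p3_ - base) * dt) + self.p4)


class AlphaDecayModel(BaseEstimator):
    """Stretched-exponential fit of log-signal versus diffusion time.

    Model (Delta in ms internally converted to s)::

        ln S(Delta) = ln p1 [- Delta/T1] - p2 * q0^2 * Delta^p3

    with the subdiffusion exponent alpha = p3 bounded to [0.5, 1.1] and p2
    the generalized diffusion constant (mm^2/s^alpha), initialized at the
    voxel's mean diffusivity.  ``q0`` is the (nominally constant) q-value of
    the experiment in rad/mm.  The optional T1 factor removes the known
    longitudinal decay accumulated over the mixing time TM ~ Delta of a
    stimulated-echo acquisition.

    The printed form of the fit expression reads "p2^2 q0^2"; consistent
    with the defining signal model (exponent -Dgen q^2 Delta^alpha) the
    linear-in-p2 form is the default and the squared reading is available
    via ``squared_dgen=True``.

    Because the receiver gain ramps steeply over the Delta grid, the noise
    of the RG-corrected log-signal is strongly heteroscedastic (the SD of
    ln S scales with 1/(RG * S)).  The log-domain residuals are therefore
    weighted by each sample's known relative precision, RG * S, by default
    (``weighting="precision"``); pass ``weighting=None`` for the plain
    unweighted log fit, or an array of custom weights.  ``rg`` supplies the
    per-sample receiver gains (taken as constant when omitted).

    Non-positive signal samples (log undefined) are dropped; fewer than 5
    surviving samples invalidate the voxel.
    """

    def __init__(self, q0=None, md_init=1e-3, amplitude_init=None,
                 alpha_init=0.9, lower=(0.0, 0.0, 0.5),
                 upper=(np.inf, np.inf, 1.1), t1_correction=False, t1=760.0,
                 squared_dgen=False, weighting="precision", rg=None,
                 tol=1e-10, max_iter=400):
        self.q0 = q0
        self.md_init = md_init
        self.amplitude_init = amplitude_init
        self.alpha_init = alpha_init
        self.lower = lower
        self.upper = upper
        self.t1_correction = t1_correction
        self.t1 = t1
        self.squared_dgen = squared_dgen
        self.weighting = weighting
        self.rg = rg
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        Delta = _column(X)            # ms
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(Delta) & np.isfinite(y) & (y > 0)
        self.n_dropped_ = int(np.isfinite(y).sum() - ok.sum())
        if ok.sum() < 5:
            return _invalid_result(self, dict(
                amplitude_=np.nan, dgen_=np.nan, alpha_=np.nan, at_bound_=False))
        rg = (np.ones(y.size) if self.rg is None
              else np.asarray(self.rg, dtype=float))
        Delta, y, rg = Delta[ok], y[ok], rg[ok]
        if self.q0 is None:
            raise ValueError("q0 (rad/mm) must be provided")
        q02 = float(self.q0) ** 2
        dt = Delta * 1e-3             # s
        t1_s = self.t1 * 1e-3
        ln_y = np.log(y)
        p1_0 = self.amplitude_init if self.amplitude_init is not None else y.max()
        if self.weighting is None:
            w = np.ones(y.size)
        elif isinstance(self.weighting, str) and self.weighting == "precision":
            w = rg * y
        else:
            w = np.asarray(self.weighting, dtype=float)[ok]
        w = w / w.mean()

        def residual(p):
            p1, p2, p3 = p
            d = p2**2 if self.squared_dgen else p2
            m = math.log(p1) - d * q02 * dt**p3
            if self.t1_correction:
                m = m - dt / t1_s
            return w * (m - ln_y)

        lo = [max(self.lower[0], 1e-30), self.lower[1], self.lower[2]]
        res = least_squares(residual, [max(p1_0, 1e-12), self.md_init, self.alpha_init],
                            bounds=(lo, list(self.upper)), method="trf",
                            xtol=self.tol, ftol=self.tol, gtol=self.tol,
                            max_nfev=self.max_iter * 10)
        p1, p2, p3 = res.x
        self.amplitude_ = float(p1)
        self.dgen_ = float(p2**2 if self.squared_dgen else p2)
        self.alpha_ = float(p3)
        self.residual_norm_ = float(np.linalg.norm(res.fun))
        self.converged_ = bool(res.status > 0)
        self.at_bound_ = bool(
            abs(p3 - self.lower[2]) < 1e-4 or abs(p3 - self.upper[2]) < 1e-4
        )
        self.valid_ = True
        return self

    def predict(self, X):
        dt = _column(X) * 1e-3
        m = np.log(self.amplitude_) - self.dgen_ * self.q0**2 * dt**self.alpha_
        if self.t1_correction:
            m = m - dt / (self.t1 * 1e-3)
        return np.exp(m)


class QSpaceBiexponentialModel(BaseEstimator):
    """Low-q two-compartment (biexponential) fit of q-space attenuation.

    Model (q cyclic, 1/mm; widths in mm)::

        S(q) = p1 exp(-2 pi^2 p2^2 q^2) + (1 - p1) exp(-2 pi^2 p3^2 q^2) + p4

    with the offset ``p4`` fixed (0.2 by default).  After fitting the two
    compartments are relabeled so that ``z_ecs_ >= z_ics_`` and ``f_ecs_``
    always refers to the wider (extracellular) compartment; this removes
    the label-swap degeneracy of the likelihood, under which initializing
    the fraction at 0.3 or 0.7 lands on mirror-image optima with identical
    residual norm.  Fits where the two widths coincide (relative gap below
    ``degenerate_tol``) are flagged ``single_compartment_``.
    """

    def __init__(self, p4=0.2, f_init=0.7, z_ecs_init=5e-3, z_ics_init=1.5e-3,
                 lower=(0.0, 0.0, 0.0), upper=(2.0, 1e-2, 1e-2),
                 degenerate_tol=0.05, tol=1e-12, max_iter=400):
        self.p4 = p4
        self.f_init = f_init
        self.z_ecs_init = z_ecs_init
        self.z_ics_init = z_ics_init
        self.lower = lower
        self.upper = upper
        self.degenerate_tol = degenerate_tol
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        q = _column(X)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(q) & np.isfinite(y)
        if ok.sum() < 10:
            return _invalid_result(self, dict(
                f_ecs_=np.nan, z_ecs_=np.nan, z_ics_=np.nan,
                single_compartment_=False, at_bound_=False))
        q, y = q[ok], y[ok]
        c2 = 2.0 * math.pi**2
        p4 = self.p4

        def residual(p):
            p1, p2, p3 = p
            return (p1 * np.exp(-c2 * p2**2 * q**2)
                    + (1.0 - p1) * np.exp(-c2 * p3**2 * q**2) + p4 - y)

        x0 = [self.f_init * y.max(), self.z_ecs_init, self.z_ics_init]
        res = least_squares(residual, x0,
                            bounds=(list(self.lower), list(self.upper)),
                            method="trf", xtol=self.tol, ftol=self.tol,
                            gtol=self.tol, max_nfev=self.max_iter * 10)
        p1, p2, p3 = res.x
        if p2 >= p3:
            f, z_ecs, z_ics = p1, p2, p3
        else:
            f, z_ecs, z_ics = 1.0 - p1, p3, p2
        self.f_ecs_ = float(min(max(f, 0.0), 1.0))
        self.z_ecs_ = float(z_ecs)
        self.z_ics_ = float(z_ics)
        widest = max(z_ecs, z_ics, 1e-30)
        self.single_compartment_ = bool((z_ecs - z_ics) / widest < self.degenerate_tol)
        self.residual_norm_ = float(np.linalg.norm(res.fun))
        self.converged_ = bool(res.status > 0)
        self.at_bound_ = bool(
            any(abs(v - b) < 1e-9 for v, b in zip(res.x, self.upper))
        )
        self.valid_ = True
        return self

    def predict(self, X):
        q = _column(X)
        c2 = 2.0 * math.pi**2
        return (self.f_ecs_ * np.exp(-c2 * self.z_ecs_**2 * q**2)
                + (1.0 - self.f_ecs_) * np.exp(-c2 * self.z_ics_**2 * q**2)
                + self.p4)


def propagator_from_signal(S, q, n_keep: int = 11, pad: int = 1):
    """Displacement profile from q-space attenuation by mirrored DFT.

    The attenuation measured on a monotone q grid starting near zero is
    extended evenly (S(-q) = S(q)), discretely Fourier transformed, and the
    real part of the central ``n_keep`` points of the resulting displacement
    profile is returned (the tails fluctuate with noise and are discarded).
    The displacement grid spacing is 1/(N dq) with N the (optionally
    zero-padded) mirrored length — the transform pair of the cyclic q
    convention, so q in 1/mm gives displacements in mm.

    Parameters
    ----------
    S : array
        Normalized attenuation values on the q grid.
    q : array
        Monotone increasing q grid (cyclic convention, 1/mm), q[0] ~ 0.
    n_keep : int
        Number of central profile points retained (odd; default 11).
    pad : int
        Zero-padding factor for the DFT (1 = none, the default).

    Returns
    -------
    (x, density) : displacement axis (mm, symmetric about 0) and the real
    part of the propagator profile.
    """
    S = np.asarray(S, dtype=float)
    q = np.asarray(q, dtype=float)
    if S.shape != q.shape or S.ndim != 1:
        raise ValueError("S and q must be matching 1D arrays")
    if np.any(np.diff(q) <= 0):
        raise ValueError("q grid must be strictly increasing")
    # resample onto a uniform grid anchored at q = 0 (the measured grid
    # starts at the lowest shell, not exactly at zero); the attenuation is
    # extended flat below the first sample
    grid = np.linspace(0.0, q[-1], S.size)
    S = np.interp(grid, q, S, left=S[0], right=S[-1])
    q = grid
    dq = float(q[1] - q[0])
    # even extension about q=0: [-qmax .. qmax]
    full = np.concatenate([S[::-1], S[1:]])
    n = full.size * int(pad)
    if n_keep > n:
        raise ValueError(f"cannot keep {n_keep} points from a {n}-point profile")
    spec = np.zeros(n, dtype=float)
    shifted = np.fft.ifftshift(full)
    half = full.size // 2 + 1
    spec[:half] = shifted[:half]
    spec[-(full.size - half):] = shifted[half:]
    profile = np.fft.fftshift(np.fft.fft(spec)) * dq
    x = np.fft.fftshift(np.fft.fftfreq(n, d=dq))
    c = n // 2
    k = n_keep // 2
    sl = slice(c - k, c + k + 1)
    return x[sl], profile.real[sl]


class LorentzianPropagatorModel(BaseEstimator):
    """Lorentzian fit of a displacement profile.

    Model::

        L(x) = p1 + (1/pi) * p2 / (x^2 + p2^2)

    where ``p2`` is the half width at half maximum y0 (mm), so the full
    width at half maximum is ``fwhm_ = 2 * y0_`` identically.  A fit pinned
    at the upper width bound is flagged via ``at_bound_``.
    """

    def __init__(self, offset_init=0.0, y0_init=2e-3, y0_max=0.1,
                 tol=1e-12, max_iter=400):
        self.offset_init = offset_init
        self.y0_init = y0_init
        self.y0_max = y0_max
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        x = _column(X)
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(x) & np.isfinite(y)
        if ok.sum() < 5:
            return _invalid_result(self, dict(offset_=np.nan, y0_=np.nan,
                                              fwhm_=np.nan, at_bound_=False))
        x, y = x[ok], y[ok]

        def residual(p):
            p1, p2 = p
            return p1 + (1.0 / math.pi) * p2 / (x**2 + p2**2) - y

        y0_start = min(max(self.y0_init, 1e-11), 0.5 * self.y0_max)
        res = least_squares(residual, [self.offset_init, y0_start],
                            bounds=([-np.inf, 1e-12], [np.inf, self.y0_max]),
                            method="trf", xtol=self.tol, ftol=self.tol,
                            gtol=self.tol, max_nfev=self.max_iter * 10)
        self.offset_ = float(res.x[0])
        self.y0_ = float(res.x[1])
        self.fwhm_ = 2.0 * self.y0_
        self.residual_norm_ = float(np.linalg.norm(res.fun))
        self.converged_ = bool(res.status > 0)
        self.at_bound_ = bool(abs(res.x[1] - self.y0_max) < 1e-9 * max(self.y0_max, 1.0))
        self.valid_ = True
        return self

    def predict(self, X):
        x = _column(X)
        return self.offset_ + (1.0 / math.pi) * self.y0_ / (x**2 + self.y0_**2)


class DiffusionTensorModel(BaseEstimator):
    """Log-linear single-shell diffusion tensor fit.

    ``X`` has one row per volume with columns (gx, gy, gz, b): the unit
    gradient direction and the b-value (s/mm^2; b=0 rows are the
    non-diffusion-weighted reference).  The six unique tensor elements and
    ln S0 are estimated by ordinary least squares on ln S; the tensor is
    diagonalized with eigenvalues sorted descending.

    Attributes include the mean diffusivity ``md_``, fractional anisotropy
    ``fa_`` (= sqrt(3/2) ||lambda - MD|| / ||lambda||), axial ``d_par_``
    (= lambda1) and radial ``d_ort_`` (= (lambda2 + lambda3)/2).
    """

    def __init__(self, weighted=False):
        self.weighted = weighted

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must be (n, 4): gx, gy, gz, b")
        ok = np.isfinite(y) & (y > 0)
        self.n_dropped_ = int(y.size - ok.sum())
        X, y = X[ok], y[ok]
        g, b = X[:, :3], X[:, 3]
        design = np.column_stack([
            np.ones_like(b),
            -b * g[:, 0] ** 2, -b * g[:, 1] ** 2, -b * g[:, 2] ** 2,
            -2 * b * g[:, 0] * g[:, 1],
            -2 * b * g[:, 0] * g[:, 2],
            -2 * b * g[:, 1] * g[:, 2],
        ])
        if np.linalg.matrix_rank(design) < 7:
            raise ValueError("rank-deficient design: need >= 6 non-collinear "
                             "directions plus a b0 volume")
        ln_y = np.log(y)
        w = y if self.weighted else None
        if w is not None:
            sol, *_ = np.linalg.lstsq(design * w[:, None], ln_y * w, rcond=None)
        else:
            sol, *_ = np.linalg.lstsq(design, ln_y, rcond=None)
        ln_s0, dxx, dyy, dzz, dxy, dxz, dyz = sol
        D = np.array([[dxx, dxy, dxz], [dxy, dyy, dyz], [dxz, dyz, dzz]])
        evals, evecs = np.linalg.eigh(D)
        order = np.argsort(evals)[::-1]
        evals, evecs = evals[order], evecs[:, order]
        md = evals.mean()
        denom = np.linalg.norm(evals)
        fa = (math.sqrt(1.5) * np.linalg.norm(evals - md) / denom
              if denom > 0 else 0.0)
        self.s0_ = float(np.exp(ln_s0))
        self.tensor_ = D
        self.eigenvalues_ = evals
        self.eigenvectors_ = evecs
        self.md_ = float(md)
        self.fa_ = float(fa)
        self.d_par_ = float(evals[0])
        self.d_ort_ = float((evals[1] + evals[2]) / 2.0)
        self.residual_norm_ = float(np.linalg.norm(design @ sol - ln_y))
        self.converged_ = True
        self.valid_ = True
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        g, b = X[:, :3], X[:, 3]
        quad = np.einsum("ni,ij,nj->n", g, self.tensor_, g)
        return self.s0_ * np.exp(-b * quad)


class RelaxometryModel(BaseEstimator):
    """Mono-exponential transverse relaxation fit, S = S0 exp(-TE/T2).

    ``kind`` is "T2star" (multi-echo gradient echo) or "T2" (spin echo);
    the machinery is identical.  ``r2_`` is 1/T2 in 1/ms.  A non-decaying
    signal is flagged (``decaying_ = False``) with ``t2_ = inf``, ``r2_ = 0``.
    """

    def __init__(self, kind="T2star", tol=1e-12, max_iter=400):
        self.kind = kind
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        te = _column(X)               # ms
        y = np.asarray(y, dtype=float)
        ok = np.isfinite(te) & np.isfinite(y) & (y > 0)
        if ok.sum() < 3:
            return _invalid_result(self, dict(s0_=np.nan, t2_=np.nan, r2_=np.nan,
                                              decaying_=False))
        te, y = te[ok], y[ok]
        # log-linear start, nonlinear refinement
        slope, intercept = np.polyfit(te, np.log(y), 1)
        if slope >= 0:
            self.s0_ = float(y.mean())
            self.t2_ = float("inf")
            self.r2_ = 0.0
            self.decaying_ = False
            self.residual_norm_ = float(np.linalg.norm(y - y.mean()))
            self.converged_ = True
            self.valid_ = True
            return self
        t2_0 = -1.0 / slope

        def residual(p):
            return p[0] * np.exp(-te / p[1]) - y

        res = least_squares(residual, [math.exp(intercept), t2_0],
                            bounds=([0.0, 1e-9], [np.inf, np.inf]),
                            method="trf", xtol=self.tol, ftol=self.tol,
                            gtol=self.tol, max_nfev=self.max_iter * 10)
        self.s0_ = float(res.x[0])
        self.t2_ = float(res.x[1])
        self.r2_ = 1.0 / self.t2_
        self.decaying_ = True
        self.residual_norm_ = float(np.linalg.norm(res.fun))
        self.converged_ = bool(res.status > 0)
        self.valid_ = True
        return self

    def predict(self, X):
        te = _column(X)
        if not np.isfinite(self.t2_):
            return np.full_like(te, self.s0_)
        return self.s0_ * np.exp(-te / self.t2_)
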