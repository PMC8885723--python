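"""Synthetic spinal-cord DWI phantoms for every acquisition protocol.

The phantom is a parametric cross-section of a fixed cord inside a fluid
filled capillary: a circular fluid annulus, a central gray-matter (GM)
"butterfly", and a white-matter (WM) rim divided into angular sectors that
stand in for named tracts.  Per-label tissue parameters drive forward
models that are exactly the fit expressions of the analysis stage, so the
simulators test estimator correctness (forward-inverse consistency), not
biophysical realism — there is no restricted-diffusion random walk here.

Magnitude-image noise is Rician: the complex signal receives independent
Gaussian noise in both channels and the magnitude is taken.  SNR is defined
against the reference (S0) intensity of the tissue parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .protocol import AcquisitionProtocol, q_from_b
from .stack import DWIStack

__all__ = [
    "TissueParams",
    "CordPhantomConfig",
    "make_cord_phantom",
    "add_rician_noise",
    "simulate_gamma_series",
    "simulate_alpha_series",
    "simulate_qsi_series",
    "simulate_dti_series",
    "simulate_gre_series",
    "dgen_for_attenuation",
]


@dataclass
class TissueParams:
    """Ground-truth generative parameters of one phantom label.

    ``gamma``/``dgen_gamma`` parameterize the pseudo-superdiffusion decay
    exp(-dgen * q^(2*gamma_d) * Delta) with q in rad/m and Delta in s
    (dgen's units depend on the exponent, as in the fitted model);
    ``alpha``/``dgen_alpha`` the subdiffusion decay exp(-dgen q^2 Delta^alpha)
    with q in rad/mm and Delta in s (dgen ~ mm^2/s^alpha); the tensor
    eigenvalues are in mm^2/s (lambda1 along the fiber axis, direction 1);
    ``z_ecs``/``z_ics`` are the q-space compartment widths in mm.
    """

    label: str
    S0: float = 1.0
    gamma: tuple = (0.8, 0.7, 0.7)
    dgen_gamma: tuple = None          # per direction; filled on demand
    alpha: tuple = (0.85, 0.8, 0.8)
    dgen_alpha: float = 0.7e-3        # mm^2 / s^alpha
    tensor_evals: tuple = (1.2e-3, 0.4e-3, 0.4e-3)
    f_ecs: float = 0.3
    z_ecs: float = 5e-3               # mm
    z_ics: float = 1.5e-3             # mm
    t1: float = 760.0                 # ms
    t2star: float = 25.0              # ms
    noise_floor: float = 0.15         # offset fraction c/A of the gamma decay

    def __post_init__(self):
        for name in ("gamma", "alpha"):
            vals = getattr(self, name)
            if np.any(np.asarray(vals) < 0) or (
                name == "gamma" and np.any(np.asarray(vals) > 1.0)
            ):
                raise ValueError(f"{name} exponents out of range: {vals}")
        if not (0.0 <= self.f_ecs <= 1.0):
            raise ValueError("f_ecs must lie in [0, 1]")
        lam = self.tensor_evals
        if not (lam[0] >= lam[1] >= lam[2] > 0):
            raise ValueError("tensor eigenvalues must satisfy l1 >= l2 >= l3 > 0")
        if not (self.z_ecs >= self.z_ics > 0):
            raise ValueError("compartment widths must satisfy z_ecs >= z_ics > 0")


def dgen_for_attenuation(attenuation, gamma, q_max_rad_m, Delta_s):
    """Generalized diffusion constant giving a target exponent at q_max."""
    return attenuation / (q_max_rad_m ** (2.0 * gamma) * Delta_s)


@dataclass
class CordPhantomConfig:
    """Geometry of the synthetic cord cross-section (sizes in voxels)."""

    shape: tuple = (1, 48, 48)        # (z, y, x)
    capillary_radius: float = 22.0
    cord_radius: float = 16.0
    gm_radius: float = 8.0            # butterfly envelope
    n_wm_tracts: int = 6
    voxel_size_mm: tuple = (1.0, 0.035, 0.035)


# label codes
BACKGROUND, FLUID, GM = 0, 1, 2
WM_FIRST = 3


def make_cord_phantom(config: CordPhantomConfig = None):
    """Label volume + per-label tissue parameters for the cord phantom.

    Returns ``(labels, names, params)`` where ``labels`` is an int array of
    shape ``config.shape``, ``names`` maps label codes to strings
    ("fluid", "gm", "wm_tract_1", ...), and ``params`` maps label codes to
    :class:`TissueParams`.  Deterministic for a fixed config.
    """
    config = config or CordPhantomConfig()
    nz, ny, nx = config.shape
    if not (config.capillary_radius > config.cord_radius >= config.gm_radius >= 0):
        raise ValueError("radii must be ordered capillary > cord >= gm >= 0")
    yy, xx = np.mgrid[0:ny, 0:nx]
    cy, cx = (ny - 1) / 2.0, (nx - 1) / 2.0
    r = np.hypot(yy - cy, xx - cx)
    theta = np.arctan2(yy - cy, xx - cx)

    sl = np.zeros((ny, nx), dtype=int)
    sl[r <= config.capillary_radius] = FLUID
    in_cord = r <= config.cord_radius
    # WM sectors
    n_tr = config.n_wm_tracts
    sector = ((theta + math.pi) / (2 * math.pi) * n_tr).astype(int) % n_tr
    sl[in_cord] = WM_FIRST + sector[in_cord]
    # GM butterfly: two lobes (ellipses) mirrored about the vertical axis
    if config.gm_radius > 0:
        a, b = config.gm_radius, 0.55 * config.gm_radius
        off = 0.45 * config.gm_radius
        for s in (-1.0, 1.0):
            lobe = (((xx - cx - s * off) / a) ** 2 + ((yy - cy) / b) ** 2) <= 1.0
            sl[lobe & in_cord] = GM
    labels = np.broadcast_to(sl, (nz, ny, nx)).copy()

    names = {FLUID: "fluid", GM: "gm"}
    names.update({WM_FIRST + i: f"wm_tract_{i + 1}" for i in range(n_tr)})

    params = {
        FLUID: TissueParams(
            label="fluid", gamma=(1.0, 1.0, 1.0), alpha=(1.0, 1.0, 1.0),
            dgen_alpha=2.0e-3, tensor_evals=(2.0e-3, 2.0e-3, 2.0e-3),
            f_ecs=1.0, z_ecs=6e-3, z_ics=5.9e-3, t1=2000.0, t2star=60.0),
        GM: TissueParams(
            label="gm", gamma=(0.85, 0.85, 0.85), alpha=(0.9, 0.9, 0.9),
            dgen_alpha=0.9e-3, tensor_evals=(0.8e-3, 0.7e-3, 0.7e-3),
            f_ecs=0.4, z_ecs=4e-3, z_ics=2e-3, t1=600.0, t2star=30.0),
    }
    for i in range(n_tr):
        g_par = 0.9 - 0.04 * i
        g_ort = g_par - 0.1
        params[WM_FIRST + i] = TissueParams(
            label=f"wm_tract_{i + 1}",
            gamma=(g_par, g_ort, g_ort),
            alpha=(0.85 - 0.02 * i, 0.8 - 0.02 * i, 0.8 - 0.02 * i),
            dgen_alpha=0.5e-3,
            tensor_evals=(1.4e-3, 0.3e-3, 0.3e-3),
            f_ecs=0.3, z_ecs=5e-3, z_ics=1.0e-3 + 2e-4 * i,
            t1=760.0, t2star=20.0 + 1.5 * i,
        )
    return labels, names, params


def add_rician_noise(signal, snr, seed=None, reference: float = 1.0, rng=None):
    """Magnitude (Rician) noise: sqrt((s+n1)^2 + n2^2), n ~ N(0, reference/snr).

    ``snr = inf`` returns the input unchanged.  Deterministic per seed.
    """
    signal = np.asarray(signal, dtype=float)
    if np.isinf(snr):
        return signal.copy()
    if rng is None:
        rng = np.random.default_rng(seed)
    sigma = reference / snr
    n1 = rng.normal(0.0, sigma, signal.shape)
    n2 = rng.normal(0.0, sigma, signal.shape)
    return np.sqrt((signal + n1) ** 2 + n2**2)


def _param_fields(labels, params, getter):
    """Broadcast a per-label scalar onto the label volume."""
    out = np.zeros(labels.shape, dtype=float)
    for code, tp in params.items():
        out[labels == code] = getter(tp)
    return out


def _finish(signal, labels, params, protocol, snr, seed, voxel_size):
    ref = np.median([tp.S0 for tp in params.values()])
    noisy = add_rician_noise(signal, snr, seed=seed, reference=ref)
    mask = labels > 0
    return DWIStack(data=noisy, voxel_size=voxel_size, protocol=protocol,
                    mask=mask)


def simulate_gamma_series(labels, params, protocol: AcquisitionProtocol,
                          snr=np.inf, seed=None,
                          voxel_size=(1.0, 0.035, 0.035),
                          attenuation_at_qmax: float = 3.0) -> DWIStack:
    """Pseudo-superdiffusion series: per-direction stretched decay in q.

    Noiseless per-voxel signal for a volume at q (rad/m) along direction d:

        S = S0 * [(1 - c) * exp(-dgen_d * q^(2*gamma_d) * Delta) + c]

    with c the tissue's noise-floor fraction.  When a tissue's
    ``dgen_gamma`` is unset it is chosen so the stretched exponent reaches
    ``attenuation_at_qmax`` at the protocol's largest q (per direction).
    """
    if protocol.kind != "gamma":
        raise ValueError("protocol.kind must be 'gamma'")
    vols = protocol.volumes()
    nz, ny, nx = labels.shape
    data = np.zeros((nz, ny, nx, len(vols)))
    dt = protocol.Delta_list[0] * 1e-3
    q_rad_m = q_from_b(vols["b_s_mm2"].to_numpy(), protocol.delta,
                       vols["Delta_ms"].to_numpy(), "radian") * 1e3
    q_max = {d: q_rad_m[vols["direction_index"] == d].max()
             for d in vols["direction_index"].unique()}
    for i, row in vols.iterrows():
        d = int(row["direction_index"])
        q = q_rad_m[i]
        vol = np.zeros((nz, ny, nx))
        for code, tp in params.items():
            gam = tp.gamma[d]
            if tp.dgen_gamma is not None:
                dg = tp.dgen_gamma[d]
            else:
                dg = dgen_for_attenuation(attenuation_at_qmax, gam, q_max[d], dt)
            c = tp.noise_floor
            s = tp.S0 * ((1 - c) * math.exp(-dg * q ** (2 * gam) * dt) + c)
            vol[labels == code] = s
        data[..., i] = vol
    return _finish(data, labels, params, protocol, snr, seed, voxel_size)


def simulate_alpha_series(labels, params, protocol: AcquisitionProtocol,
                          snr=np.inf, apply_T1: bool = False, seed=None,
                          voxel_size=(1.0, 0.035, 0.035)) -> DWIStack:
    """Subdiffusion series: stretched decay in Delta at constant g.

    Noiseless signal S = S0 * exp(-dgen * q^2 * Delta^alpha_d) with q in
    rad/mm from the per-volume b-value, optionally multiplied by
    exp(-Delta/T1); each Delta volume is then scaled by its receiver gain
    (relative to the first) before noise, mirroring the acquisition.
    """
    if protocol.kind != "alpha":
        raise ValueError("protocol.kind must be 'alpha'")
    vols = protocol.volumes()
    q_rad_mm = q_from_b(vols["b_s_mm2"].to_numpy(), protocol.delta,
                        vols["Delta_ms"].to_numpy(), "radian")
    # q must be (nominally) constant within each direction
    for d in vols["direction_index"].unique():
        qd = q_rad_mm[vols["direction_index"] == d]
        if (qd.max() - qd.min()) / qd.mean() > 0.05:
            raise ValueError("q varies by more than 5% across the Delta grid")
    nz, ny, nx = labels.shape
    data = np.zeros((nz, ny, nx, len(vols)))
    rg = vols["rg"].to_numpy()
    for i, row in vols.iterrows():
        d = int(row["direction_index"])
        dt = row["Delta_ms"] * 1e-3
        vol = np.zeros((nz, ny, nx))
        for code, tp in params.items():
            s = tp.S0 * math.exp(-tp.dgen_alpha * q_rad_mm[i] ** 2
                                 * dt ** tp.alpha[d])
            if apply_T1:
                s *= math.exp(-row["Delta_ms"] / tp.t1)
            vol[labels == code] = s
        data[..., i] = vol * (rg[i] / rg[0])
    return _finish(data, labels, params, protocol, snr, seed, voxel_size)


def simulate_qsi_series(labels, params, protocol: AcquisitionProtocol,
                        snr=np.inf, seed=None, noise_floor: float = 0.2,
                        voxel_size=(1.0, 0.035, 0.035)) -> DWIStack:
    """Q-space series: two-Gaussian compartment decay along one direction.

    Noiseless signal (q cyclic, 1/mm):

        S = S0 * [f exp(-2 pi^2 q^2 z_ecs^2) + (1-f) exp(-2 pi^2 q^2 z_ics^2)
                  + noise_floor]

    The additive ``noise_floor`` (default 0.2) mirrors the fixed offset of
    the magnitude-data fit; pass 0 for an ideal normalized decay.
    """
    if protocol.kind != "qsi":
        raise ValueError("protocol.kind must be 'qsi'")
    vols = protocol.volumes()
    if len(protocol.directions) != 1:
        raise ValueError("q-space series uses a single gradient direction")
    q_cyc = q_from_b(vols["b_s_mm2"].to_numpy(), protocol.delta,
                     vols["Delta_ms"].to_numpy(), "cyclic")
    nz, ny, nx = labels.shape
    data = np.zeros((nz, ny, nx, len(vols)))
    c2 = 2.0 * math.pi**2
    for i in range(len(vols)):
        q = q_cyc[i]
        vol = np.zeros((nz, ny, nx))
        for code, tp in params.items():
            s = tp.S0 * (tp.f_ecs * math.exp(-c2 * q**2 * tp.z_ecs**2)
                         + (1 - tp.f_ecs) * math.exp(-c2 * q**2 * tp.z_ics**2)
                         + noise_floor)
            vol[labels == code] = s
        data[..., i] = vol
    return _finish(data, labels, params, protocol, snr, seed, voxel_size)


def simulate_dti_series(labels, params, protocol: AcquisitionProtocol,
                        snr=np.inf, seed=None,
                        voxel_size=(1.0, 0.035, 0.035)) -> DWIStack:
    """Single-shell tensor series: S = S0 exp(-b g^T D g).

    The per-label tensor is diagonal in the protocol frame with lambda1
    along direction 1 (the fiber/B0 axis).
    """
    if protocol.kind != "dti":
        raise ValueError("protocol.kind must be 'dti'")
    vols = protocol.volumes()
    nz, ny, nx = labels.shape
    data = np.zeros((nz, ny, nx, len(vols)))
    for i, row in vols.iterrows():
        d = int(row["direction_index"])
        g = np.asarray(protocol.directions[d], float)
        b = row["b_s_mm2"]
        vol = np.zeros((nz, ny, nx))
        for code, tp in params.items():
            D = np.diag(tp.tensor_evals)
            vol[labels == code] = tp.S0 * math.exp(-b * float(g @ D @ g))
        data[..., i] = vol
    return _finish(data, labels, params, protocol, snr, seed, voxel_size)


def simulate_gre_series(labels, params, te_list, snr=np.inf, seed=None):
    """Multi-echo gradient-echo magnitude series, S = S0 exp(-TE/T2*).

    Returns a plain 4D array (z, y, x, echo); TE in ms.
    """
    te = np.asarray(te_list, dtype=float)
    nz, ny, nx = labels.shape
    data = np.zeros((nz, ny, nx, te.size))
    for code, tp in params.items():
        decay = tp.S0 * np.exp(-te / tp.t2star)
        data[labels == code] = decay
    ref = np.median([tp.S0 for tp in params.values()])
    return add_rician_noise(data, snr, seed=seed, reference=ref)
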