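"""Map-level fitting: apply the voxel estimators over a masked stack.

Each ``fit_*_map`` function groups the stack's volumes by gradient
direction through the acquisition protocol, normalizes the signal as the
corresponding model expects, loops the matching estimator over the masked
voxels and returns named :class:`~tadmri.stack.ParametricMap` objects.
Voxels that cannot be fitted are flagged invalid in the output masks (never
silently zeroed).  Voxels whose residual norm falls above a configurable
percentile can be masked out of downstream ROI statistics via
``residual_percentile``.
"""

from __future__ import annotations

import numpy as np

from .models import (
    AlphaDecayModel,
    DiffusionTensorModel,
    GammaDecayModel,
    LorentzianPropagatorModel,
    QSpaceBiexponentialModel,
    RelaxometryModel,
    propagator_from_signal,
)
from .protocol import q_from_b
from .stack import DWIStack, ParametricMap, normalize_attenuation

__all__ = [
    "fit_gamma_voxel",
    "fit_alpha_voxel",
    "fit_gamma_map",
    "fit_alpha_map",
    "fit_qsi_map",
    "fit_dti_map",
    "fit_relaxometry_map",
]


def fit_gamma_voxel(S_norm, q_rad_mm, Delta_ms, **model_kw) -> GammaDecayModel:
    """Stretched-exponential fit of one voxel along one direction."""
    return GammaDecayModel(Delta=Delta_ms, **model_kw).fit(q_rad_mm, S_norm)


def fit_alpha_voxel(S, Delta_ms, q0_rad_mm, **model_kw) -> AlphaDecayModel:
    """Subdiffusion fit of one voxel along one direction (linear-signal input)."""
    return AlphaDecayModel(q0=q0_rad_mm, **model_kw).fit(Delta_ms, S)


def _direction_groups(stack: DWIStack):
    vols = stack.index
    for d in sorted(vols["direction_index"].unique()):
        sub = vols[vols["direction_index"] == d]
        yield int(d), sub.index.to_numpy(), sub


def _qc_mask(residual, valid, residual_percentile):
    if residual_percentile is None:
        return valid
    r = residual[valid]
    if r.size == 0:
        return valid
    cut = np.nanpercentile(r, residual_percentile)
    return valid & (residual <= cut)


def fit_gamma_map(stack: DWIStack, mask=None, background_roi=None,
                  md_map=None, residual_percentile=None, **model_kw):
    """Per-voxel, per-direction pseudo-superdiffusion exponent maps.

    The stack is background-corrected and normalized to its lowest-b volume
    per direction; q is taken in the radian convention.  ``md_map`` (scalar
    or array, mm^2/s) supplies the baseline diffusivity D0 of the reference
    correction term — absorbed by the free amplitude, so gamma itself is
    insensitive to it.

    Returns a dict of ParametricMap: gamma_1..3, dgen_1..3, residual,
    converged, plus "valid" mask bookkeeping.
    """
    if stack.protocol.kind != "gamma":
        raise ValueError("protocol.kind must be 'gamma'")
    mask = stack.mask if mask is None else np.asarray(mask, bool)
    shape = stack.data.shape[:3]
    out = {}
    residual = np.full(shape, np.nan)
    converged = np.zeros(shape, bool)
    valid_all = np.ones(shape, bool)
    md = np.broadcast_to(np.asarray(md_map if md_map is not None else 0.0,
                                    float), shape)
    for d, vol_idx, sub in _direction_groups(stack):
        b = sub["b_s_mm2"].to_numpy()
        order = np.argsort(b)
        vol_idx, b = vol_idx[order], b[order]
        q = q_from_b(b, stack.protocol.delta, sub["Delta_ms"].to_numpy()[order],
                     "radian")
        norm, valid = normalize_attenuation(
            _substack(stack, vol_idx), background_roi=background_roi, s0_index=0)
        gam = np.full(shape, np.nan)
        dgen = np.full(shape, np.nan)
        for vox in np.argwhere(mask & valid):
            z, y, x = vox
            est = GammaDecayModel(Delta=float(sub["Delta_ms"].iloc[0]),
                                  d0=float(md[z, y, x]), **model_kw)
            est.fit(q, norm[z, y, x, :])
            if est.valid_:
                gam[z, y, x] = est.gamma_
                dgen[z, y, x] = est.dgen_
                residual[z, y, x] = np.nansum(
                    [residual[z, y, x], est.residual_norm_])
                converged[z, y, x] |= est.converged_
            else:
                valid[z, y, x] = False
        valid_all &= valid
        vm = mask & valid & np.isfinite(gam)
        out[f"gamma_{d + 1}"] = ParametricMap(f"gamma_{d + 1}", "1", gam, vm,
                                              "gamma stretched-exponential fit")
        out[f"dgen_{d + 1}"] = ParametricMap(f"dgen_{d + 1}", "a.u.", dgen, vm,
                                             "gamma stretched-exponential fit")
    final = _qc_mask(residual, mask & valid_all, residual_percentile)
    out["residual"] = ParametricMap("residual", "1", residual,
                                    mask & valid_all, "gamma fit")
    out["converged"] = ParametricMap("converged", "bool",
                                     converged.astype(float), mask, "gamma fit")
    out["valid"] = ParametricMap("valid", "bool", final.astype(float),
                                 np.ones(shape, bool), "gamma fit")
    return out


def _substack(stack: DWIStack, vol_idx):
    """A lightweight view of selected volumes with a matching RG table."""

    class _Sub:
        data = stack.data[..., vol_idx]
        mask = stack.mask
        index = stack.index.iloc[vol_idx].reset_index(drop=True)

    return _Sub()


def fit_alpha_map(stack: DWIStack, segmentation=None, md_by_tissue=None,
                  mask=None, background_roi=None, residual_percentile=None,
                  **model_kw):
    """Per-voxel subdiffusion exponent maps, fitted per tissue class.

    ``segmentation`` maps tissue names to boolean masks (e.g. {"wm": ...,
    "gm_fluid": ...}); each class is fitted with its own mean-diffusivity
    initialization from ``md_by_tissue`` (median MD per tissue, mm^2/s).
    Signals are background-corrected and receiver-gain-corrected; no S0
    division (the amplitude is free).  Voxels not covered by any class are
    flagged invalid.
    """
    if stack.protocol.kind != "alpha":
        raise ValueError("protocol.kind must be 'alpha'")
    mask = stack.mask if mask is None else np.asarray(mask, bool)
    shape = stack.data.shape[:3]
    if segmentation is None:
        segmentation = {"all": mask}
    md_by_tissue = md_by_tissue or {}
    data = stack.data.astype(float).copy()
    rg = stack.index["rg"].to_numpy()
    if background_roi is not None:
        bg = data[np.asarray(background_roi, bool)].mean(axis=0)
        data -= bg[None, None, None, :]
    data *= (rg[0] / rg)[None, None, None, :]

    out = {}
    residual = np.full(shape, np.nan)
    covered = np.zeros(shape, bool)
    for d, vol_idx, sub in _direction_groups(stack):
        Delta = sub["Delta_ms"].to_numpy()
        q = q_from_b(sub["b_s_mm2"].to_numpy(), stack.protocol.delta, Delta,
                     "radian")
        q0 = float(np.sqrt(np.mean(q**2)))
        alph = np.full(shape, np.nan)
        for tissue, tmask in segmentation.items():
            tmask = np.asarray(tmask, bool) & mask
            covered |= tmask
            md0 = float(md_by_tissue.get(tissue, 1e-3))
            rg_d = sub["rg"].to_numpy()
            for vox in np.argwhere(tmask):
                z, y, x = vox
                est = AlphaDecayModel(q0=q0, md_init=md0, rg=rg_d, **model_kw)
                est.fit(Delta, data[z, y, x, vol_idx])
                if est.valid_:
                    alph[z, y, x] = est.alpha_
                    residual[z, y, x] = np.nansum(
                        [residual[z, y, x], est.residual_norm_])
        vm = covered & np.isfinite(alph)
        out[f"alpha_{d + 1}"] = ParametricMap(f"alpha_{d + 1}", "1", alph, vm,
                                              "alpha stretched-exponential fit")
    final = _qc_mask(residual, covered, residual_percentile)
    out["residual"] = ParametricMap("residual", "1", residual, covered, "alpha fit")
    out["valid"] = ParametricMap("valid", "bool", final.astype(float),
                                 np.ones(shape, bool), "alpha fit")
    return out


def fit_qsi_map(stack: DWIStack, mask=None, background_roi=None,
                n_keep: int = 11, normalize: bool = True, **model_kw):
    """Q-space maps: f_ecs, Z_ecs, Z_ics (biexponential) and FWHM (propagator).

    Widths are reported in micrometres.  ``normalize=False`` skips the
    background/S0 normalization for input that is already expressed as an
    attenuation (e.g. noiseless synthetic series with unit S0).
    """
    if stack.protocol.kind != "qsi":
        raise ValueError("protocol.kind must be 'qsi'")
    mask = stack.mask if mask is None else np.asarray(mask, bool)
    shape = stack.data.shape[:3]
    vols = stack.index
    b = vols["b_s_mm2"].to_numpy()
    order = np.argsort(b)
    q = q_from_b(b[order], stack.protocol.delta,
                 vols["Delta_ms"].to_numpy()[order], "cyclic")
    if normalize:
        norm, valid = normalize_attenuation(_substack(stack, order),
                                            background_roi=background_roi,
                                            s0_index=0)
    else:
        norm = stack.data[..., order]
        valid = stack.mask.copy()
    f_map = np.full(shape, np.nan)
    ze = np.full(shape, np.nan)
    zi = np.full(shape, np.nan)
    fwhm = np.full(shape, np.nan)
    for vox in np.argwhere(mask & valid):
        z, y, x = vox
        sig = norm[z, y, x, :]
        bi = QSpaceBiexponentialModel(**model_kw).fit(q, sig)
        if bi.valid_:
            f_map[z, y, x] = bi.f_ecs_
            ze[z, y, x] = bi.z_ecs_ * 1e3
            zi[z, y, x] = bi.z_ics_ * 1e3
        xs, prof = propagator_from_signal(sig, q, n_keep=n_keep)
        lo = LorentzianPropagatorModel().fit(xs, prof)
        if lo.valid_:
            fwhm[z, y, x] = lo.fwhm_ * 1e3
    vm = mask & valid
    prov = "q-space low-q biexponential / mirrored-DFT Lorentzian"
    return {
        "f_ecs": ParametricMap("f_ecs", "1", f_map, vm & np.isfinite(f_map), prov),
        "Z_ecs": ParametricMap("Z_ecs", "um", ze, vm & np.isfinite(ze), prov),
        "Z_ics": ParametricMap("Z_ics", "um", zi, vm & np.isfinite(zi), prov),
        "FWHM": ParametricMap("FWHM", "um", fwhm, vm & np.isfinite(fwhm), prov),
    }


def fit_dti_map(stack: DWIStack, mask=None):
    """Tensor maps MD, FA, Dpar, Dort (mm^2/s; FA unitless)."""
    if stack.protocol.kind != "dti":
        raise ValueError("protocol.kind must be 'dti'")
    mask = stack.mask if mask is None else np.asarray(mask, bool)
    shape = stack.data.shape[:3]
    vols = stack.index
    dirs = np.asarray([stack.protocol.directions[int(d)]
                       for d in vols["direction_index"]])
    X = np.column_stack([dirs, vols["b_s_mm2"].to_numpy()])
    md = np.full(shape, np.nan)
    fa = np.full(shape, np.nan)
    dpar = np.full(shape, np.nan)
    dort = np.full(shape, np.nan)
    for vox in np.argwhere(mask):
        z, y, x = vox
        est = DiffusionTensorModel().fit(X, stack.data[z, y, x, :])
        md[z, y, x] = est.md_
        fa[z, y, x] = est.fa_
        dpar[z, y, x] = est.d_par_
        dort[z, y, x] = est.d_ort_
    vm = mask & np.isfinite(md)
    return {
        "MD": ParametricMap("MD", "mm^2/s", md, vm, "log-linear tensor fit"),
        "FA": ParametricMap("FA", "1", fa, vm, "log-linear tensor fit"),
        "Dpar": ParametricMap("Dpar", "mm^2/s", dpar, vm, "log-linear tensor fit"),
        "Dort": ParametricMap("Dort", "mm^2/s", dort, vm, "log-linear tensor fit"),
    }


def fit_relaxometry_map(data, te_list, mask=None, kind="T2star"):
    """T2*/T2 and R2*/R2 maps from a multi-echo magnitude series.

    ``data`` is (z, y, x, echo); TE in ms.  R2* is 1/T2* in 1/ms.
    """
    data = np.asarray(data, float)
    te = np.asarray(te_list, float)
    shape = data.shape[:3]
    mask = np.ones(shape, bool) if mask is None else np.asarray(mask, bool)
    t2 = np.full(shape, np.nan)
    r2 = np.full(shape, np.nan)
    for vox in np.argwhere(mask):
        z, y, x = vox
        est = RelaxometryModel(kind=kind).fit(te, data[z, y, x, :])
        if est.valid_:
            t2[z, y, x] = est.t2_
            r2[z, y, x] = est.r2_
    vm = mask & np.isfinite(r2)
    name = "T2star" if kind == "T2star" else "T2"
    return {
        name: ParametricMap(name, "ms", t2, vm & np.isfinite(t2), "mono-exponential"),
        f"R2{'star' if kind == 'T2star' else ''}": ParametricMap(
            f"R2{'star' if kind == 'T2star' else ''}", "1/ms", r2, vm,
            "mono-exponential"),
    }
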