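"""Scalar invariants of directional stretched-exponential exponents.

From a triplet (e1, e2, e3) of exponents measured along three orthogonal
directions (the first parallel to the main fiber axis / B0), the rotationally
motivated summaries are:

* mean        M   = (e1 + e2 + e3) / 3
* anisotropy  A   = 3 [(e1-M)^2 + (e2-M)^2 + (e3-M)^2] / (2 (e1^2+e2^2+e3^2))
* parallel    par = e1
* orthogonal  ort = (e2 + e3) / 2

A lies in [0, 1] for any non-negative triplet: it is 0 for equal exponents
and 1 when a single component carries everything.  The formula is the
squared (FA-style, but un-rooted) normalized dispersion; the square-rooted
variant is available for comparison via ``sqrt_variant=True``.
"""

from __future__ import annotations

import numpy as np

__all__ = ["exponent_invariants", "invariant_maps"]


def exponent_invariants(e1, e2, e3, sqrt_variant: bool = False):
    """Invariants of an exponent triplet; broadcasting over arrays.

    All-zero triplets yield anisotropy NaN (0/0 is not fake isotropy).

    Returns
    -------
    dict with keys "mean", "anisotropy", "par", "ort".
    """
    e1, e2, e3 = np.broadcast_arrays(
        np.asarray(e1, float), np.asarray(e2, float), np.asarray(e3, float)
    )
    if np.any((np.asarray([e1, e2, e3]) < 0) & np.isfinite([e1, e2, e3])):
        raise ValueError("exponents must be non-negative")
    m = (e1 + e2 + e3) / 3.0
    # normalize by the largest component first: A is scale-invariant, and
    # this keeps the ratio finite for subnormal or huge exponents
    scale = np.maximum(np.maximum(e1, e2), e3)
    with np.errstate(invalid="ignore", divide="ignore"):
        u1, u2, u3 = e1 / scale, e2 / scale, e3 / scale
        um = (u1 + u2 + u3) / 3.0
        ss = u1**2 + u2**2 + u3**2
        disp = (u1 - um) ** 2 + (u2 - um) ** 2 + (u3 - um) ** 2
        a = np.where(scale > 0, 3.0 * disp / (2.0 * ss), np.nan)
    if sqrt_variant:
        a = np.sqrt(a)
    squeeze = np.isscalar(m) or m.ndim == 0
    out = {
        "mean": m,
        "anisotropy": a,
        "par": e1,
        "ort": (e2 + e3) / 2.0,
    }
    if squeeze:
        out = {k: float(v) for k, v in out.items()}
    return out


def invariant_maps(maps, prefix: str = "gamma", sqrt_variant: bool = False):
    """Apply :func:`exponent_invariants` voxel-wise to three exponent maps.

    Parameters
    ----------
    maps : sequence of three arrays or ParametricMap-likes
        Direction-1/2/3 exponent maps (direction 1 parallel to the fibers).
    prefix : str
        Name stem for the output maps ("gamma" or "alpha").

    Returns
    -------
    dict of ParametricMap: M<prefix>, A<prefix>, <prefix>_par, <prefix>_ort,
    with the anisotropy mask excluding all-zero voxels.
    """
    from .stack import ParametricMap

    arrs = [np.asarray(getattr(m, "values", m), float) for m in maps]
    base_masks = [getattr(m, "mask", None) for m in maps]
    mask = np.ones(arrs[0].shape, bool)
    for bm in base_masks:
        if bm is not None:
            mask &= bm
    inv = exponent_invariants(*arrs, sqrt_variant=sqrt_variant)
    a_mask = mask & np.isfinite(inv["anisotropy"])
    prov = f"invariants({prefix})"
    return {
        f"M{prefix}": ParametricMap(f"M{prefix}", "1", np.where(mask, inv["mean"], np.nan), mask, prov),
        f"A{prefix}": ParametricMap(f"A{prefix}", "1", np.where(a_mask, inv["anisotropy"], np.nan), a_mask, prov),
        f"{prefix}_par": ParametricMap(f"{prefix}_par", "1", np.where(mask, inv["par"], np.nan), mask, prov),
        f"{prefix}_ort": ParametricMap(f"{prefix}_ort", "1", np.where(mask, inv["ort"], np.nan), mask, prov),
    }
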