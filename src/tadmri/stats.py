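"""Validation statistics: MD-threshold ROIs, ROI summaries, Pearson
correlation tables, regression against R2*, and the area-fraction z-test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy import ndimage

__all__ = [
    "ROISet",
    "rois_from_md",
    "interface_roi",
    "roi_means",
    "pearson_table",
    "significance_stars",
    "regress_gamma_vs_r2star",
    "fraction_ztest",
]


@dataclass
class ROISet:
    labels: np.ndarray        # int label image/volume, 0 = unassigned
    names: dict               # label code -> name
    provenance: str = ""
    empty_labels: tuple = ()

    def mask(self, name: str) -> np.ndarray:
        code = {v: k for k, v in self.names.items()}[name]
        return self.labels == code


def rois_from_md(md_values, thresholds, names=None, mask=None) -> ROISet:
    """Bin voxels into labeled ROIs by mean-diffusivity bands.

    ``thresholds`` must be strictly increasing; ``len(thresholds) + 1``
    bands result, named via ``names`` (low-MD band first by default).
    Empty bands are flagged, not errors.
    """
    md = np.asarray(getattr(md_values, "values", md_values), float)
    thresholds = [float(t) for t in thresholds]
    if sorted(set(thresholds)) != thresholds:
        raise ValueError("thresholds must be strictly increasing")
    mask = np.isfinite(md) if mask is None else (np.asarray(mask, bool)
                                                 & np.isfinite(md))
    bands = np.digitize(md, thresholds) + 1
    labels = np.where(mask, bands, 0)
    n = len(thresholds) + 1
    if names is None:
        names = [f"band_{i + 1}" for i in range(n)]
    if len(names) != n:
        raise ValueError(f"need {n} names for {len(thresholds)} thresholds")
    name_map = {i + 1: nm for i, nm in enumerate(names)}
    empty = tuple(nm for code, nm in name_map.items()
                  if not (labels == code).any())
    return ROISet(labels=labels, names=name_map,
                  provenance=f"MD thresholds {thresholds}", empty_labels=empty)


def interface_roi(roiset: ROISet, name_a: str, name_b: str,
                  width: int = 2) -> np.ndarray:
    """Boundary band between two ROIs (e.g. the gm-wm interface).

    The band is the intersection of the ``width``-voxel dilations of the
    two ROIs — voxels within ``width`` of both tissues.
    """
    a = roiset.mask(name_a)
    b = roiset.mask(name_b)
    struct = ndimage.generate_binary_structure(a.ndim, 1)
    da = ndimage.binary_dilation(a, struct, iterations=width)
    db = ndimage.binary_dilation(b, struct, iterations=width)
    return da & db


def roi_means(maps, rois: ROISet) -> pd.DataFrame:
    """Mean +/- SD of each metric over each ROI.

    ``maps`` is a dict name -> ParametricMap or array.  Invalid voxels
    (outside the map's mask, or non-finite) are excluded and counted.
    Empty ROIs yield NaN with n = 0.
    """
    records = {}
    for code, roi_name in rois.names.items():
        roi = rois.labels == code
        row = {}
        for metric, m in maps.items():
            vals = np.asarray(getattr(m, "values", m), float)
            mmask = getattr(m, "mask", None)
            sel = roi & np.isfinite(vals)
            if mmask is not None:
                sel &= mmask
            v = vals[sel]
            row[f"{metric}_mean"] = float(v.mean()) if v.size else np.nan
            row[f"{metric}_sd"] = float(v.std(ddof=0)) if v.size else np.nan
            row[f"{metric}_n"] = int(v.size)
        records[roi_name] = row
    return pd.DataFrame.from_dict(records, orient="index")


def significance_stars(p: float) -> str:
    """Star convention: * <0.05, ** <0.01, *** <0.005, **** <0.001."""
    for stars, cut in (("****", 0.001), ("***", 0.005), ("**", 0.01), ("*", 0.05)):
        if p < cut:
            return stars
    return ""


def pearson_table(mri_summary: pd.DataFrame,
                  histo_summary: pd.DataFrame) -> pd.DataFrame:
    """Pearson r (with two-tailed P from the t distribution, n-2 df) between
    every MRI metric column and every histology feature column.

    Rows must be matched ROIs (index-aligned; n >= 3).  Zero-variance
    columns yield NaN entries (r undefined) rather than errors.

    Returns a DataFrame indexed by MRI metric with a column MultiIndex
    (feature, {"r", "P", "n", "stars"}).
    """
    mri, histo = mri_summary.align(histo_summary, join="inner", axis=0)
    if len(mri) < 3:
        raise ValueError("need at least 3 matched ROI rows")
    out = {}
    for mcol in mri.columns:
        row = {}
        for hcol in histo.columns:
            x = mri[mcol].to_numpy(float)
            y = histo[hcol].to_numpy(float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < 3 or np.std(x[ok]) == 0 or np.std(y[ok]) == 0:
                r, p = np.nan, np.nan
            else:
                r, p = sps.pearsonr(x[ok], y[ok])
            row[(hcol, "r")] = r
            row[(hcol, "P")] = p
            row[(hcol, "n")] = n
            row[(hcol, "stars")] = significance_stars(p) if np.isfinite(p) else ""
        out[mcol] = row
    table = pd.DataFrame.from_dict(out, orient="index")
    table.columns = pd.MultiIndex.from_tuples(table.columns)
    return table


def regress_gamma_vs_r2star(gamma_means, r2star_means) -> dict:
    """Ordinary least-squares line of a gamma-metric on R2* across ROIs."""
    x = np.asarray(r2star_means, float)
    y = np.asarray(gamma_means, float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError("need at least 3 ROI means")
    if np.std(x) == 0:
        raise ValueError("constant predictor: regression undefined")
    res = sps.linregress(x, y)
    return dict(slope=float(res.slope), intercept=float(res.intercept),
                r=float(res.rvalue), P=float(res.pvalue), n=int(x.size))


def fraction_ztest(f1: float, n1: int, f2: float, n2: int) -> dict:
    """Two-proportion z-test (pooled variance, two-tailed) on area fractions."""
    if n1 <= 0 or n2 <= 0:
        raise ValueError("sample sizes must be positive")
    for f in (f1, f2):
        if not (0.0 <= f <= 1.0):
            raise ValueError("fractions must lie in [0, 1]")
    if f1 == f2:
        return dict(z=0.0, P=1.0)
    pooled = (f1 * n1 + f2 * n2) / (n1 + n2)
    se = np.sqrt(pooled * (1 - pooled) * (1.0 / n1 + 1.0 / n2))
    z = (f1 - f2) / se
    p = 2.0 * sps.norm.sf(abs(z))
    return dict(z=float(z), P=float(p))
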