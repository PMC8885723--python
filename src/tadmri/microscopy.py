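"""Synthetic toluidine-blue-like micrographs of packed myelinated axons.

Axons are non-overlapping disks (axoplasm / intracellular space) wrapped in
a myelin annulus of fixed g-ratio, placed by random sequential adsorption
on an extracellular background.  Debris objects that deliberately violate
the downstream selection rules (speckles below the area threshold,
elongated bars above the shape threshold, and mottled blobs above the
intensity-uniformity threshold) can be sprinkled in.  The generator returns
the image together with a per-axon ground-truth table, so morphometry
recovery is testable without real histology.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skimage.draw import disk as _disk

__all__ = ["MicroscopyPhantomSpec", "make_microscopy_phantom", "PackingError"]


class PackingError(RuntimeError):
    """Target axon count could not be placed; carries the achieved count."""

    def __init__(self, placed, target):
        super().__init__(
            f"could only place {placed} of {target} axons; "
            "reduce the target density or the diameters"
        )
        self.placed = placed
        self.target = target


@dataclass
class MicroscopyPhantomSpec:
    """Parameters of one synthetic micrograph.

    Intensities are 8-bit gray levels, darkest for myelin (toluidine blue
    stains the sheath most strongly).  ``g_ratio`` is the inner/outer
    diameter ratio of the myelinated fiber; diameters are Gaussian with the
    given mean/SD, truncated at 3 pixels.  ``free_area_layout`` controls
    where the axon-free space sits: "dispersed" spreads axons over the full
    field, "clustered" packs them into a sub-region leaving one large free
    area (same axon count, hence same global density, different local
    packing).
    """

    field_size_um: float = 20.0
    pixel_size_um: float = 0.033
    diameter_mean_um: float = 1.5
    diameter_sd_um: float = 0.3
    n_axons: int = 100
    g_ratio: float = 0.7
    intensity_levels: dict = field(default_factory=lambda: {
        "myelin": 40, "ics": 110, "ecs": 180, "other": 240})
    debris_count: int = 0
    free_area_layout: str = "dispersed"
    clustered_fill: float = 0.55      # fraction of the field packed when clustered
    seed: int = 0
    max_attempts_per_axon: int = 400

    def __post_init__(self):
        if self.pixel_size_um <= 0:
            raise ValueError("pixel size must be positive")
        if len(set(self.intensity_levels.values())) != len(self.intensity_levels):
            raise ValueError("intensity levels must be pairwise distinct")
        if not (0 < self.g_ratio <= 1):
            raise ValueError("g-ratio must lie in (0, 1]")
        if self.free_area_layout not in ("dispersed", "clustered"):
            raise ValueError("free_area_layout must be 'dispersed' or 'clustered'")


def make_microscopy_phantom(spec: MicroscopyPhantomSpec):
    """Render the micrograph and its ground truth.

    Returns
    -------
    image : 2D uint8 array
    truth : pandas.DataFrame
        One row per axon: id, cy_px, cx_px, diameter_um (inner), area_um2.
    info : dict
        n_axons, area fractions by class (summing to 1 over the field),
        pixel size, field shape.
    """
    rng = np.random.default_rng(spec.seed)
    n_px = int(round(spec.field_size_um / spec.pixel_size_um))
    lvl = spec.intensity_levels
    image = np.full((n_px, n_px), lvl["ecs"], dtype=np.uint8)

    min_diam_um = 3.0 * spec.pixel_size_um
    # sample diameters first so the distribution is layout-independent
    diams = rng.normal(spec.diameter_mean_um, spec.diameter_sd_um, spec.n_axons)
    diams = np.clip(diams, min_diam_um, None)

    if spec.free_area_layout == "clustered":
        # axons confined to a disk covering `clustered_fill` of the area
        c = n_px / 2.0
        r_lim = n_px / 2.0 * math.sqrt(spec.clustered_fill) * 1.35
    centers, outer_r_px = [], []
    placed_rows = []
    for i, d_in in enumerate(diams):
        r_in = d_in / 2.0 / spec.pixel_size_um          # px
        r_out = r_in / spec.g_ratio
        ok = False
        for _ in range(spec.max_attempts_per_axon):
            if spec.free_area_layout == "clustered":
                rho = r_lim * math.sqrt(rng.random())
                ang = rng.random() * 2 * math.pi
                cy = c + rho * math.sin(ang)
                cx = c + rho * math.cos(ang)
            else:
                cy = rng.uniform(r_out, n_px - r_out)
                cx = rng.uniform(r_out, n_px - r_out)
            if not (r_out <= cy <= n_px - r_out and r_out <= cx <= n_px - r_out):
                continue
            if centers:
                cs = np.asarray(centers)
                rs = np.asarray(outer_r_px)
                if np.any(np.hypot(cs[:, 0] - cy, cs[:, 1] - cx) < rs + r_out + 1.0):
                    continue
            ok = True
            break
        if not ok:
            raise PackingError(i, spec.n_axons)
        centers.append((cy, cx))
        outer_r_px.append(r_out)
        rr, cc = _disk((cy, cx), r_out, shape=image.shape)
        image[rr, cc] = lvl["myelin"]
        rr, cc = _disk((cy, cx), r_in, shape=image.shape)
        image[rr, cc] = lvl["ics"]
        area_px = rr.size
        placed_rows.append(dict(
            id=i, cy_px=cy, cx_px=cx, diameter_um=float(d_in),
            area_um2=float(area_px) * spec.pixel_size_um**2))

    _add_debris(image, spec, rng, centers, outer_r_px)

    truth = pd.DataFrame(placed_rows)
    total = image.size
    # classify every pixel to its nearest class level so the fractions are
    # exhaustive even where debris carries intermediate gray values
    names = sorted(lvl, key=lvl.get)
    levels = np.array([lvl[n] for n in names], float)
    cuts = (levels[:-1] + levels[1:]) / 2.0
    bands = np.digitize(image.astype(float), cuts)
    fractions = {
        name: float((bands == i).sum()) / total for i, name in enumerate(names)
    }
    info = dict(
        n_axons=spec.n_axons,
        fractions=fractions,
        pixel_size_um=spec.pixel_size_um,
        shape=image.shape,
        field_area_mm2=(n_px * spec.pixel_size_um * 1e-3) ** 2,
    )
    return image, truth, info


def _add_debris(image, spec, rng, centers, outer_r_px):
    """Objects that must be rejected by the selection rules."""
    n_px = image.shape[0]
    lvl = spec.intensity_levels
    kinds = ["bar", "mottled", "speckle"]
    cs = np.asarray(centers) if centers else np.zeros((0, 2))
    rs = np.asarray(outer_r_px) if centers else np.zeros(0)

    def free_spot(margin):
        for _ in range(200):
            cy = rng.uniform(margin, n_px - margin)
            cx = rng.uniform(margin, n_px - margin)
            if cs.size == 0 or np.all(
                np.hypot(cs[:, 0] - cy, cs[:, 1] - cx) > rs + margin + 1.0
            ):
                return cy, cx
        return None

    for k in range(spec.debris_count):
        kind = kinds[k % len(kinds)]
        if kind == "bar":
            length = max(int(12 * 3.0), 36)
            width = max(length // 12, 1)  # >= 10:1 aspect
            spot = free_spot(length / 2 + 2)
            if spot is None:
                continue
            cy, cx = int(spot[0]), int(spot[1])
            y0, y1 = cy - width // 2, cy + (width + 1) // 2
            x0, x1 = cx - length // 2, cx + length // 2
            image[max(y0, 0):y1, max(x0, 0):x1] = lvl["ics"]
        elif kind == "mottled":
            r = max(int(0.6 / spec.pixel_size_um / 2), 6)
            spot = free_spot(r + 2)
            if spot is None:
                continue
            rr, cc = _disk(spot, r, shape=image.shape)
            noisy = rng.normal(lvl["ics"], 0.8 * lvl["ics"], rr.size)
            image[rr, cc] = np.clip(noisy, 1, 255).astype(np.uint8)
        else:  # speckle below any sensible area threshold
            spot = free_spot(3)
            if spot is None:
                continue
            rr, cc = _disk(spot, 1.2, shape=image.shape)
            image[rr, cc] = lvl["ics"]
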