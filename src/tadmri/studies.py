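"""Self-contained validation studies run by the acceptance machinery.

Each function generates its inputs with the package's own synthetic-data
generators under the study conditions of the acquisition protocols (Table-1
style grids, printed receiver-gain schedule, Rician noise at the stated
SNR), executes the corresponding estimator or pipeline stage, and returns
the measured quantities as plain floats.  Nothing here reads external data.
"""

from __future__ import annotations

import numpy as np

from .metrics import exponent_invariants
from .microscopy import MicroscopyPhantomSpec, make_microscopy_phantom
from .models import (
    AlphaDecayModel,
    GammaDecayModel,
    LorentzianPropagatorModel,
    QSpaceBiexponentialModel,
    propagator_from_signal,
)
from .morphometry import compute_morphometry, eld, extract_axons, segment_tissue
from .protocol import (
    ALPHA_DELTAS,
    ALPHA_RG,
    alpha_protocol,
    b_from_gradient,
    gamma_protocol,
    q_from_b,
    qsi_protocol,
)
from .maps import fit_gamma_map
from .stats import pearson_table
from .synthetic import (
    CordPhantomConfig,
    add_rician_noise,
    make_cord_phantom,
    simulate_gamma_series,
)

__all__ = [
    "table1_b_checks",
    "invariant_algebra_study",
    "gamma_recovery_study",
    "alpha_recovery_study",
    "alpha_t1_agreement_study",
    "qsi_recovery_study",
    "propagator_width_study",
    "morphometry_recovery_study",
    "eld_layout_study",
    "end_to_end_correlation_study",
]

#: printed effective gradients (mT/m) at delta = 2 ms, Delta = 40 ms and the
#: corresponding printed effective b values (s/mm^2)
TABLE1_GB = {
    "b0_all": (73.7, 61.2),
    "dti_ortho_max": (372.4, 1561.2),
    "dti_oblique_max": (418.5, 1971.9),
    "gamma_inplane_max": (869.9, 8521.2),
    "gamma_longitudinal_max": (918.4, 9496.6),
    "qsi_min": (81.5, 74.7),
    "qsi_max": (1122.0, 14171.0),
}


def table1_b_checks() -> dict:
    """Recompute every printed effective b from its printed effective g."""
    return {name: b_from_gradient(g, 2.0, 40.0)
            for name, (g, _) in TABLE1_GB.items()}


def invariant_algebra_study(n: int = 100_000, seed: int = 0) -> dict:
    """Anisotropy algebra on degenerate and random exponent triplets."""
    rng = np.random.default_rng(seed)
    t = rng.random((3, n)) * rng.choice([0.1, 1.0, 10.0], size=n)
    a = exponent_invariants(t[0], t[1], t[2])["anisotropy"]
    return {
        "a_equal_triplet": exponent_invariants(0.8, 0.8, 0.8)["anisotropy"],
        "a_single_component": exponent_invariants(1.0, 0.0, 0.0)["anisotropy"],
        "a_random_min": float(np.nanmin(a)),
        "a_random_max": float(np.nanmax(a)),
    }


def _gamma_grids():
    proto = gamma_protocol()
    vols = proto.volumes()
    grids = []
    for d in range(3):
        sub = vols[vols.direction_index == d]
        grids.append(q_from_b(sub["b_s_mm2"].to_numpy(), proto.delta,
                              sub["Delta_ms"].to_numpy(), "radian"))
    return grids


def _eq15_signal(q_rad_mm, gamma, attenuation=3.0, Delta_ms=40.0,
                 amplitude=0.85, offset=0.15):
    q_si = q_rad_mm * 1e3
    dt = Delta_ms * 1e-3
    dgen = attenuation / (q_si.max() ** (2 * gamma) * dt)
    return amplitude * np.exp(-dgen * q_si ** (2 * gamma) * dt) + offset


def gamma_recovery_study(gammas=(0.6, 0.8, 1.0), snr: float = 30.0,
                         n_seeds: int = 100, seed: int = 0) -> dict:
    """Pseudo-superdiffusion exponent recovery on the gamma protocol grid.

    Noiseless fits per direction per gamma, plus a Monte-Carlo at the
    stated SNR pooled over all gammas, directions and seeds.
    """
    grids = _gamma_grids()
    noiseless_errs, mc_errs = [], []
    ss = np.random.SeedSequence(seed)
    sub_seed = int(ss.generate_state(1)[0] % (2**31))
    k = 0
    for gamma in gammas:
        for q in grids:
            S = _eq15_signal(q, gamma)
            est = GammaDecayModel().fit(q, S)
            noiseless_errs.append(abs(est.gamma_ - gamma))
            for i in range(n_seeds):
                noisy = add_rician_noise(S, snr=snr, seed=sub_seed + k)
                k += 1
                mc_errs.append(abs(GammaDecayModel().fit(q, noisy).gamma_
                                   - gamma))
    return {
        "noiseless_max_abs_err": float(np.max(noiseless_errs)),
        "median_abs_err": float(np.median(mc_errs)),
        "n_fits": len(mc_errs),
    }


def _alpha_setup():
    proto = alpha_protocol()
    vols = proto.volumes()
    sub = vols[vols.direction_index == 0]
    Delta = sub["Delta_ms"].to_numpy()
    q = q_from_b(sub["b_s_mm2"].to_numpy(), proto.delta, Delta, "radian")
    q0 = float(np.sqrt(np.mean(q**2)))
    return Delta, q0


def alpha_recovery_study(alphas=(0.7, 0.9), snr: float = 30.0,
                         n_seeds: int = 100, seed: int = 0,
                         dgen: float = 0.7e-3) -> dict:
    """Subdiffusion exponent recovery on the Delta grid with the printed
    receiver-gain schedule (noise enters after RG scaling, as acquired)."""
    Delta, q0 = _alpha_setup()
    rg = np.asarray(ALPHA_RG)
    dt = Delta * 1e-3
    ss = np.random.SeedSequence(seed + 1)
    sub_seed = int(ss.generate_state(1)[0] % (2**31))
    noiseless_errs, mc_errs = [], []
    k = 0
    for alpha in alphas:
        S = np.exp(-dgen * q0**2 * dt**alpha)
        est = AlphaDecayModel(q0=q0, rg=rg).fit(Delta, S)
        noiseless_errs.append(abs(est.alpha_ - alpha))
        for i in range(n_seeds):
            scaled = S * rg / rg[0]
            noisy = add_rician_noise(scaled, snr=snr, seed=sub_seed + k)
            k += 1
            corrected = noisy * rg[0] / rg
            mc_errs.append(abs(AlphaDecayModel(q0=q0, rg=rg).fit(
                Delta, corrected).alpha_ - alpha))
    return {
        "noiseless_max_abs_err": float(np.max(noiseless_errs)),
        "median_abs_err": float(np.median(mc_errs)),
        "n_fits": len(mc_errs),
    }


def alpha_t1_agreement_study(alphas=(0.7, 0.9), t1_ms: float = 760.0,
                             dgen: float = 0.7e-3) -> dict:
    """Fit T1-decayed subdiffusion signals with and without the known
    exp(-Delta/T1) factor and measure the disagreement on alpha.

    Deterministic (noiseless): isolates the structural effect of the
    longitudinal-decay term on the stretched-exponential fit.
    """
    Delta, q0 = _alpha_setup()
    dt = Delta * 1e-3
    diffs = {}
    for alpha in alphas:
        S = np.exp(-dgen * q0**2 * dt**alpha) * np.exp(-Delta / t1_ms)
        on = AlphaDecayModel(q0=q0, t1_correction=True, t1=t1_ms).fit(Delta, S)
        off = AlphaDecayModel(q0=q0).fit(Delta, S)
        diffs[alpha] = abs(on.alpha_ - off.alpha_)
    return {
        "max_abs_alpha_diff": float(max(diffs.values())),
        "per_alpha": {str(a): float(d) for a, d in diffs.items()},
    }


def _qsi_grid():
    proto = qsi_protocol()
    vols = proto.volumes()
    return q_from_b(vols["b_s_mm2"].to_numpy(), proto.delta,
                    vols["Delta_ms"].to_numpy(), "cyclic")


def qsi_recovery_study(f: float = 0.3, z_ecs: float = 5e-3,
                       z_ics: float = 1.5e-3) -> dict:
    """Noiseless biexponential compartment recovery and the resolution of
    the fraction-initialization indetermination (0.3 vs 0.7)."""
    q = _qsi_grid()
    c2 = 2 * np.pi**2
    S = (f * np.exp(-c2 * q**2 * z_ecs**2)
         + (1 - f) * np.exp(-c2 * q**2 * z_ics**2) + 0.2)
    fits = {f0: QSpaceBiexponentialModel(f_init=f0).fit(q, S)
            for f0 in (0.3, 0.7)}
    a, b = fits[0.3], fits[0.7]
    return {
        "f_ecs_rel_err_pct": 100 * abs(a.f_ecs_ - f) / f,
        "z_ecs_rel_err_pct": 100 * abs(a.z_ecs_ - z_ecs) / z_ecs,
        "z_ics_rel_err_pct": 100 * abs(a.z_ics_ - z_ics) / z_ics,
        "init_residual_norm_diff": abs(a.residual_norm_ - b.residual_norm_),
        "init_f_ecs_diff": abs(a.f_ecs_ - b.f_ecs_),
        "init_z_ecs_rel_diff": abs(a.z_ecs_ - b.z_ecs_) / z_ecs,
    }


def propagator_width_study(z: float = 1.5e-3, snr: float = 30.0,
                           n_seeds: int = 50, seed: int = 0) -> dict:
    """End-to-end displacement-profile width recovery.

    A single Gaussian restriction of width ``z`` (mm) generates the
    attenuation; the mirrored-DFT profile is fitted with the Lorentzian and
    the median pipeline FWHM is compared against the true propagator FWHM
    (2 sqrt(2 ln 2) z).
    """
    q = _qsi_grid()
    S = np.exp(-2 * np.pi**2 * q**2 * z**2)
    true_fwhm = 2 * np.sqrt(2 * np.log(2)) * z
    ss = np.random.SeedSequence(seed + 2)
    sub_seed = int(ss.generate_state(1)[0] % (2**31))
    fwhms, identity_dev = [], 0.0
    for i in range(n_seeds):
        noisy = add_rician_noise(S, snr=snr, seed=sub_seed + i)
        x, prof = propagator_from_signal(noisy, q, n_keep=11)
        est = LorentzianPropagatorModel().fit(x, prof)
        fwhms.append(est.fwhm_)
        identity_dev = max(identity_dev, abs(est.fwhm_ - 2 * est.y0_))
    med = float(np.median(fwhms))
    return {
        "true_fwhm_um": 1e3 * true_fwhm,
        "median_fwhm_um": 1e3 * med,
        "fwhm_rel_err_pct": 100 * abs(med - true_fwhm) / true_fwhm,
        "fwhm_identity_max_dev": identity_dev,
    }


def morphometry_recovery_study(seed: int = 0, n_axons: int = 500,
                               pixel_size_um: float = 0.033,
                               field_size_um: float = 80.0,
                               diameter_mean_um: float = 1.5,
                               diameter_sd_um: float = 0.3) -> dict:
    """Morphometry on a seeded micrograph against generator ground truth."""
    spec = MicroscopyPhantomSpec(
        field_size_um=field_size_um, pixel_size_um=pixel_size_um,
        diameter_mean_um=diameter_mean_um, diameter_sd_um=diameter_sd_um,
        n_axons=n_axons, seed=int(seed % (2**31)), debris_count=6)
    image, truth, info = make_microscopy_phantom(spec)
    seg = segment_tissue(image, thresholds=(75, 145, 210))
    table, labels = extract_axons(seg.masks["ics"], image, pixel_size_um)
    roi = np.ones(image.shape, bool)
    res = compute_morphometry(table, labels, roi, pixel_size_um)
    true_diam = float(truth["diameter_um"].mean())
    true_dens = n_axons / info["field_area_mm2"]
    return {
        "ax_diam_um": res.ax_diam_um,
        "true_ax_diam_um": true_diam,
        "ax_diam_bias_um": abs(res.ax_diam_um - true_diam),
        "ax_dens_per_mm2": res.ax_dens_per_mm2,
        "true_ax_dens_per_mm2": true_dens,
        "ax_dens_rel_err_pct": 100 * abs(res.ax_dens_per_mm2 - true_dens)
                               / true_dens,
        "fraction_sum_dev": abs(sum(seg.fractions.values()) - 1.0),
        "n_kept": res.n_kept,
    }


def eld_layout_study(seed: int = 0) -> dict:
    """ELD ordering between clustered and dispersed free-space layouts at
    matched axon count."""
    out = {}
    for layout in ("clustered", "dispersed"):
        spec = MicroscopyPhantomSpec(
            field_size_um=30.0, pixel_size_um=0.05, diameter_mean_um=1.0,
            diameter_sd_um=0.15, n_axons=90, seed=int(seed % (2**31)),
            free_area_layout=layout)
        image, truth, info = make_microscopy_phantom(spec)
        seg = segment_tissue(image, thresholds=(75, 145, 210))
        table, labels = extract_axons(seg.masks["ics"], image, 0.05)
        out[layout] = eld(table, labels, np.ones(image.shape, bool), 0.05)
    out["eld_clustered_over_dispersed"] = out["clustered"] / out["dispersed"]
    return out


#: increasing axon-diameter means (um) across the six synthetic WM tracts
TRACT_DIAMETERS_UM = (0.9, 1.1, 1.3, 1.5, 1.7, 1.9)


def _gamma_for_diameter(d_um: float) -> float:
    # monotone map emulating the positive Mgamma-AxDiam association
    return 0.55 + 0.20 * (d_um - 0.9)


def end_to_end_correlation_study(snr: float = 30.0, seed: int = 0) -> dict:
    """Six-tract synthetic study: does the pipeline recover the positive
    association between the mean pseudo-superdiffusion exponent and axon
    diameter?

    Ground-truth gamma increases with the tract's axon diameter; the MRI
    arm simulates and fits the gamma series, the histology arm renders and
    measures one micrograph per tract, and the Pearson table between the
    per-tract Mgamma and AxDiam summaries is returned.
    """
    ss = np.random.SeedSequence(seed + 3)
    s_mri, s_histo = (int(x % (2**31)) for x in ss.generate_state(2))

    # --- MRI arm -------------------------------------------------------
    cfg = CordPhantomConfig(shape=(1, 40, 40), capillary_radius=18.0,
                            cord_radius=14.0, gm_radius=6.0)
    labels, names, params = make_cord_phantom(cfg)
    code_by_name = {v: k for k, v in names.items()}
    for i, d_um in enumerate(TRACT_DIAMETERS_UM):
        tp = params[code_by_name[f"wm_tract_{i + 1}"]]
        g_par = _gamma_for_diameter(d_um)
        tp.gamma = (g_par, max(g_par - 0.08, 0.0), max(g_par - 0.08, 0.0))
    proto = gamma_protocol()
    stack = simulate_gamma_series(labels, params, proto, snr=snr, seed=s_mri)
    maps = fit_gamma_map(stack)
    from .metrics import invariant_maps

    inv = invariant_maps([maps["gamma_1"], maps["gamma_2"], maps["gamma_3"]],
                         prefix="gamma")
    import pandas as pd

    rows = {}
    for i in range(6):
        roi = labels == code_by_name[f"wm_tract_{i + 1}"]
        sel = roi & inv["Mgamma"].mask
        rows[f"wm_tract_{i + 1}"] = {
            "Mgamma": float(inv["Mgamma"].values[sel].mean())}
    mri_summary = pd.DataFrame.from_dict(rows, orient="index")

    # --- histology arm -------------------------------------------------
    hrows = {}
    for i, d_um in enumerate(TRACT_DIAMETERS_UM):
        n_ax = min(45, int(70 / d_um**2))
        spec = MicroscopyPhantomSpec(
            field_size_um=20.0, pixel_size_um=0.05, diameter_mean_um=d_um,
            diameter_sd_um=0.15 * d_um, n_axons=n_ax,
            seed=(s_histo + i) % (2**31))
        image, truth, info = make_microscopy_phantom(spec)
        seg = segment_tissue(image, thresholds=(75, 145, 210))
        table, lab_img = extract_axons(seg.masks["ics"], image, 0.05)
        res = compute_morphometry(table, lab_img, np.ones(image.shape, bool),
                                  0.05)
        hrows[f"wm_tract_{i + 1}"] = {"AxDiam": res.ax_diam_um}
    histo_summary = pd.DataFrame.from_dict(hrows, orient="index")

    table = pearson_table(mri_summary, histo_summary)
    return {
        "r_mgamma_axdiam": float(table.loc["Mgamma", ("AxDiam", "r")]),
        "p_mgamma_axdiam": float(table.loc["Mgamma", ("AxDiam", "P")]),
        "n_tracts": 6,
    }
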