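"""Acquisition-protocol data model and b/q conversion arithmetic.

A pulsed-gradient stimulated-echo (PGSTE) experiment is described by the
gradient pulse width ``delta`` (ms), the gradient separation ``Delta`` (ms),
the effective gradient strength ``g`` (mT/m) and the derived diffusion
weighting ``b`` (s/mm^2).  Two q-value conventions coexist in the anomalous
diffusion literature and both are supported explicitly:

* ``radian``:  q = gamma_H * g * delta          [rad/mm internally]
* ``cyclic``:  q = gamma_H * g * delta / (2 pi) [1/mm]

Every consumer of a q array states which convention it expects; silent
mixing is forbidden by construction (conversion is a single multiplication
by 2 pi, done here and nowhere else).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

#: proton gyromagnetic ratio, rad s^-1 T^-1
GAMMA_H = 2.675e8

PROTOCOL_KINDS = ("gamma", "alpha", "dti", "qsi", "relaxometry")
Q_CONVENTIONS = ("radian", "cyclic")


class ProtocolError(ValueError):
    """An acquisition protocol violates its invariants."""


def _check_timing(delta: float, Delta) -> None:
    Delta = np.asarray(Delta, dtype=float)
    if delta <= 0:
        raise ProtocolError(f"gradient pulse width delta must be positive, got {delta}")
    if np.any(Delta <= delta / 3.0):
        raise ProtocolError(
            f"gradient separation Delta must exceed delta/3 = {delta / 3.0:g} ms"
        )


def b_from_gradient(g, delta, Delta, gamma_h: float = GAMMA_H):
    """Effective b-value of a rectangular PGSTE pulse pair.

    b = (gamma_H * g * delta)^2 * (Delta - delta/3)

    Parameters
    ----------
    g : float or array
        Effective gradient strength, mT/m (>= 0).
    delta, Delta : float
        Pulse width and separation, ms.
    gamma_h : float
        Gyromagnetic ratio, rad s^-1 T^-1.

    Returns
    -------
    b : float or array, s/mm^2
    """
    g = np.asarray(g, dtype=float)
    if np.any(g < 0):
        raise ProtocolError("gradient strength must be non-negative")
    _check_timing(delta, Delta)
    q_rad_per_m = gamma_h * (g * 1e-3) * (delta * 1e-3)
    b_si = q_rad_per_m**2 * ((np.asarray(Delta, float) - delta / 3.0) * 1e-3)  # s/m^2
    out = b_si * 1e-6  # s/mm^2
    return float(out) if np.isscalar(g) or out.ndim == 0 else out


def q_from_b(b, delta, Delta, convention: str = "cyclic"):
    """Invert b = 4 pi^2 q^2 (Delta - delta/3) for the q-value.

    Returns q in 1/mm (``cyclic``) or rad/mm (``radian``).
    """
    if convention not in Q_CONVENTIONS:
        raise ValueError(f"unknown q convention {convention!r}")
    b = np.asarray(b, dtype=float)
    if np.any(b < 0):
        raise ProtocolError("b-value must be non-negative")
    _check_timing(delta, Delta)
    tau_s = (np.asarray(Delta, float) - delta / 3.0) * 1e-3
    q_cyc = np.sqrt(b / (4.0 * math.pi**2 * tau_s))  # 1/mm
    out = q_cyc if convention == "cyclic" else 2.0 * math.pi * q_cyc
    return float(out) if out.ndim == 0 else out


def q_from_gradient(g, delta, convention: str = "cyclic", gamma_h: float = GAMMA_H):
    """q-value directly from the gradient strength (g in mT/m, delta in ms)."""
    if convention not in Q_CONVENTIONS:
        raise ValueError(f"unknown q convention {convention!r}")
    q_rad_per_mm = gamma_h * (np.asarray(g, float) * 1e-3) * (delta * 1e-3) * 1e-3
    out = q_rad_per_mm if convention == "radian" else q_rad_per_mm / (2.0 * math.pi)
    return float(out) if out.ndim == 0 else out


@dataclass
class AcquisitionProtocol:
    """Single source of truth for the acquisition arithmetic of one experiment.

    ``g_list`` and ``b_list`` are per-direction lists: ``g_list[d][k]`` is the
    effective gradient strength of shell ``k`` along direction ``d`` (for the
    alpha kind, shell index enumerates the Delta grid instead).
    """

    kind: str
    delta: float                      # ms
    Delta_list: list                  # ms
    directions: list                  # unit 3-vectors
    g_list: list                      # mT/m, per direction per shell
    b_list: list = None               # s/mm^2, per direction per shell
    mixing_time_list: list = None     # ms
    RG_list: list = None              # receiver gain, one per Delta entry (alpha)
    TR: float = 3.5                   # s
    TE: float = 12.0                  # ms
    gamma_H: float = GAMMA_H
    q_convention: str = "radian"
    te_list: list = field(default_factory=list)  # ms, relaxometry only

    def __post_init__(self):
        if self.b_list is None:
            self.b_list = [
                [
                    b_from_gradient(g, self.delta, D, self.gamma_H)
                    for g, D in zip(gs, self._delta_grid(len(gs)))
                ]
                for gs in self.g_list
            ]
        self.validate()

    def _delta_grid(self, n_shells: int):
        """Delta value for each shell index."""
        if self.kind == "alpha":
            return list(self.Delta_list)
        return [self.Delta_list[0]] * n_shells

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        problems = []
        if self.kind not in PROTOCOL_KINDS:
            problems.append(f"unknown kind {self.kind!r}")
        if self.q_convention not in Q_CONVENTIONS:
            problems.append(f"unknown q convention {self.q_convention!r}")
        if self.kind != "relaxometry":
            if self.delta >= min(self.Delta_list):
                problems.append("delta must be smaller than every Delta")
            for d, v in enumerate(self.directions):
                if abs(np.linalg.norm(v) - 1.0) > 1e-6:
                    problems.append(f"direction {d} is not unit-norm: {v}")
            for gs in self.g_list:
                if np.any(np.asarray(gs) < 0):
                    problems.append("negative gradient strength")
            if self.kind == "alpha":
                if self.RG_list is None or len(self.RG_list) != len(self.Delta_list):
                    problems.append("alpha protocol needs one receiver gain per Delta")
            # stored b must agree with the arithmetic to 0.5 %
            for d, (gs, bs) in enumerate(zip(self.g_list, self.b_list)):
                for k, (g, b) in enumerate(zip(gs, bs)):
                    D = self._delta_grid(len(gs))[k]
                    b_ref = b_from_gradient(g, self.delta, D, self.gamma_H)
                    if b_ref > 0 and abs(b - b_ref) / b_ref > 5e-3:
                        problems.append(
                            f"stored b[{d}][{k}]={b:.1f} disagrees with "
                            f"b_from_gradient={b_ref:.1f} by more than 0.5%"
                        )
        if problems:
            raise ProtocolError("; ".join(problems))

    # -- volume table ----------------------------------------------------
    def volumes(self) -> pd.DataFrame:
        """One row per acquired volume: (direction, Delta, g, b, RG, TM)."""
        rows = []
        for d, gs in enumerate(self.g_list):
            deltas = self._delta_grid(len(gs))
            for k, (g, D) in enumerate(zip(gs, deltas)):
                di = self.Delta_list.index(D) if self.kind == "alpha" else 0
                rows.append(
                    dict(
                        direction_index=d,
                        shell=k,
                        Delta_ms=D,
                        g_mT_m=g,
                        b_s_mm2=self.b_list[d][k],
                        rg=(self.RG_list[di] if self.RG_list else 1.0),
                        mixing_time_ms=(
                            self.mixing_time_list[di]
                            if self.mixing_time_list
                            else np.nan
                        ),
                    )
                )
        return pd.DataFrame(rows)

    @property
    def n_volumes(self) -> int:
        return sum(len(gs) for gs in self.g_list)

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        def pyify(v):
            if isinstance(v, (list, tuple)):
                return [pyify(x) for x in v]
            if isinstance(v, (np.floating, np.integer)):
                return v.item()
            return v

        return {k: pyify(v) for k, v in asdict(self).items()}

    @classmethod
    def from_dict(cls, d: dict) -> "AcquisitionProtocol":
        return cls(**d)

    def save(self, path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict()))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path) -> "AcquisitionProtocol":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)


# ---------------------------------------------------------------------------
# Factory functions for the four PGSTE experiments (and T2* relaxometry).
# Gradient strengths are the printed effective values; b is recomputed from
# them, which agrees with the printed effective b to better than 0.5 %.
# ---------------------------------------------------------------------------

_ORTHO3 = [(1.0, 0.0, 0.0), (0.0, 1.0, 0.0), (0.0, 0.0, 1.0)]
_SQ2 = 1.0 / math.sqrt(2.0)

#: receiver gains used for the subdiffusion Delta grid
ALPHA_RG = [64.0, 64.0, 64.0, 64.0, 421.147, 855.654, 2801.08]
ALPHA_DELTAS = [40.0, 60.0, 80.0, 150.0, 300.0, 500.0, 800.0]


def gamma_protocol(n_b: int = 17) -> AcquisitionProtocol:
    """Pseudo-superdiffusion experiment: g ramps at constant Delta = 40 ms.

    Three orthogonal directions, 16 b-values plus the b0 reference
    (effective b 61.2 to 8521.2 / 8521.2 / 9496.6 s/mm^2).
    """
    g_max = [869.9, 869.9, 918.4]
    g_list = [list(np.linspace(73.7, gm, n_b)) for gm in g_max]
    return AcquisitionProtocol(
        kind="gamma",
        delta=2.0,
        Delta_list=[40.0],
        mixing_time_list=[34.0],
        directions=_ORTHO3,
        g_list=g_list,
        TR=3.5,
        TE=12.0,
        q_convention="radian",
    )


def alpha_protocol() -> AcquisitionProtocol:
    """Subdiffusion experiment: Delta ramps at constant gradient strength.

    One volume per Delta per direction, all at the printed effective
    diffusion gradient (80.8 / 80.8 / 80.7 mT/m; the separately printed
    lower effective g belongs to the b0 reference volume, which the
    amplitude-free fit does not use).  The printed maximum effective b
    (1493.6 s/mm^2 at Delta = 800 ms) is reproduced exactly.
    """
    g_const = [80.8, 80.8, 80.7]
    g_list = [[g] * len(ALPHA_DELTAS) for g in g_const]
    return AcquisitionProtocol(
        kind="alpha",
        delta=2.0,
        Delta_list=ALPHA_DELTAS,
        mixing_time_list=[d - 6.0 for d in ALPHA_DELTAS],
        directions=_ORTHO3,
        g_list=g_list,
        RG_list=list(ALPHA_RG),
        TR=3.5,
        TE=12.0,
        q_convention="radian",
    )


def dti_protocol() -> AcquisitionProtocol:
    """Six-direction single-shell tensor experiment plus b0 (Delta = 40 ms)."""
    directions = _ORTHO3 + [(_SQ2, _SQ2, 0.0), (_SQ2, 0.0, _SQ2), (0.0, _SQ2, _SQ2)]
    b_max = [1561.2, 1561.2, 2142.0, 1561.2, 1971.9, 1971.9]
    tau = 40.0 - 2.0 / 3.0
    g_list = []
    for b in b_max:
        q = math.sqrt(b * 1e6 / (tau * 1e-3))  # rad/m
        g = q / (GAMMA_H * 2e-3) * 1e3  # mT/m
        g_list.append([73.7, g])
    return AcquisitionProtocol(
        kind="dti",
        delta=2.0,
        Delta_list=[40.0],
        mixing_time_list=[34.0],
        directions=directions,
        g_list=g_list,
        TR=3.5,
        TE=12.0,
        q_convention="radian",
    )


def qsi_protocol(n_q: int = 31) -> AcquisitionProtocol:
    """Q-space experiment: single direction, 30 b-values plus b0.

    Effective g ramps 81.5 -> 1122 mT/m (b 74.7 -> 14171 s/mm^2);
    q reaches ~95.5 mm^-1 in the cyclic convention.
    """
    g_list = [list(np.linspace(81.5, 1122.0, n_q))]
    return AcquisitionProtocol(
        kind="qsi",
        delta=2.0,
        Delta_list=[40.0],
        mixing_time_list=[34.0],
        directions=[(1.0, 0.0, 0.0)],
        g_list=g_list,
        TR=3.5,
        TE=12.0,
        q_convention="cyclic",
    )


GRE_TE_LIST = [1.8, 2, 4, 6, 8, 10, 12, 14, 16, 18, 20, 25, 30, 35, 40]


def gre_protocol() -> AcquisitionProtocol:
    """Multi-echo gradient-echo protocol for T2* mapping (15 TE values)."""
    return AcquisitionProtocol(
        kind="relaxometry",
        delta=1.0,
        Delta_list=[40.0],
        directions=[(1.0, 0.0, 0.0)],
        g_list=[[0.0] * len(GRE_TE_LIST)],
        b_list=[[0.0] * len(GRE_TE_LIST)],
        TR=1.2,
        TE=GRE_TE_LIST[0],
        te_list=list(GRE_TE_LIST),
        q_convention="radian",
    )
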