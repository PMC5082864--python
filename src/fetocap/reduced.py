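"""Closed-form (reduced-order) oxygen-transfer model for a capillary.

For a capillary of radius R0 and length L carrying fully developed flow
at pressure drop dP, with oxygen held at the maternal concentration
c_mat on the wall, the total oxygen transfer rate N falls into one of
three regimes depending on the effective Péclet number Pe_eff:

* Lévêque (boundary-layer) regime:  N_flow,1 = alpha*c_mat*(D^2*B*dP*L^2/R)^{1/3}
  with alpha = (12*pi^2)^{1/3} / Gamma(4/3) ~ 5.5 — transfer confined to a
  thin wall layer, N ∝ dP^{1/3}.
* Equilibrated regime:  N_flow,2 = c_mat*B*dP/R = c_mat*B*Q — the outflow
  leaves fully oxygenated, N ∝ Q.
* Diffusion-limited bound:  N_max = D*A*c_mat / (R0*ln(1+d/R0)) — transfer
  through the annular villous tissue of thickness d surrounding the
  capillary, independent of flow.

A single regression formula interpolates between the two flow-limited
asymptotes, and a harmonic-style correction caps it by N_max.  These
formulas treat a (possibly branched) capillary as a single equivalent
tube of radius R0 = sqrt(V/(pi*L)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd

from .params import TransportParameters, effective_peclet

__all__ = [
    "LEVEQUE_PREFACTOR",
    "CapillarySummary",
    "TransferPrediction",
    "annular_diffusion_bound",
    "classify_regime",
    "equilibrated_transfer",
    "equivalent_radius",
    "leveque_transfer",
    "poiseuille_resistance",
    "predict_transfer",
    "read_summaries",
    "regression_flow",
    "sensitivity_factor",
    "villous_corrected_transfer",
    "write_summaries",
]

#: Lévêque prefactor alpha = (12*pi^2)^{1/3} / Gamma(4/3) ~ 5.5.
LEVEQUE_PREFACTOR = (12.0 * math.pi**2) ** (1.0 / 3.0) / math.gamma(4.0 / 3.0)

Regime = Literal[
    "flow_limited_leveque",
    "flow_limited_equilibrated",
    "diffusion_limited",
    "crossover",
]


@dataclass
class CapillarySummary:
    """Geometric/flow summary of one capillary (one skeletonized image).

    All lengths in um, areas um^2, volumes um^3, resistance Pa s/um^3.
    At least one of ``V_cap`` and ``R0`` must be given; when both are
    present, the explicit ``R0`` wins for the transfer formulas.
    ``L_path`` is the longest inflow-to-outflow path (defaults to L) and
    enters only the regime inequality.
    """

    L: float
    d: float
    A: float
    label: str = ""
    L_path: float | None = None
    V_cap: float | None = None
    R0: float | None = None
    R_resistance: float | None = None
    N_max_numeric: float | None = None

    def __post_init__(self) -> None:
        for name in ("L", "d", "A"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.V_cap is None and self.R0 is None:
            raise ValueError("one of V_cap, R0 is required")
        for name in ("L_path", "V_cap", "R0", "R_resistance", "N_max_numeric"):
            v = getattr(self, name)
            if v is not None and v <= 0:
                raise ValueError(f"{name} must be positive when given")
        if self.L_path is None:
            self.L_path = self.L

    @property
    def radius(self) -> float:
        """Effective radius: explicit R0 if set, else sqrt(V/(pi*L))."""
        if self.R0 is not None:
            return self.R0
        return equivalent_radius(self.V_cap, self.L)

    def resistance(self, mu: float) -> float:
        """Vascular resistance: measured if available, else Poiseuille."""
        if self.R_resistance is not None:
            return self.R_resistance
        return poiseuille_resistance(mu, self.L, self.radius)


@dataclass
class TransferPrediction:
    """Per-capillary, per-pressure-drop oxygen-transfer prediction (ug/s)."""

    label: str
    dP: float
    N_flow_1: float
    N_flow_2: float
    N_flow_regression: float
    N_max: float
    N_corrected: float
    N_ratio: float
    c_inner_fraction: float
    K1: float
    K2: float
    regime: Regime
    Pe_eff: float

    def to_dict(self) -> dict:
        return asdict(self)


# ---------------------------------------------------------------------------
# elementary formulas
# ---------------------------------------------------------------------------

def poiseuille_resistance(mu: float, L: float, R0: float) -> float:
    """Poiseuille resistance of a straight tube, R = 8*mu*L/(pi*R0^4)."""
    if mu <= 0 or L <= 0 or R0 <= 0:
        raise ValueError("mu, L and R0 must be positive")
    return 8.0 * mu * L / (math.pi * R0**4)


def equivalent_radius(V_cap: float, L: float) -> float:
    """Radius of the cylinder with volume V_cap and length L."""
    if V_cap <= 0 or L <= 0:
        raise ValueError("V_cap and L must be positive")
    return math.sqrt(V_cap / (math.pi * L))


def leveque_transfer(
    params: TransportParameters, L: float, resistance: float, dP: float
) -> float:
    """Boundary-layer (Lévêque) transfer N_flow,1 in ug/s.

    N_flow,1 = alpha * c_mat * (D^2 * B * dP * L^2 / R)^{1/3}.
    """
    if L <= 0 or resistance <= 0:
        raise ValueError("L and resistance must be positive")
    if dP < 0:
        raise ValueError("dP must be nonnegative")
    n_g_per_s = (
        LEVEQUE_PREFACTOR
        * params.c_mat
        * (params.D**2 * params.B * dP * L**2 / resistance) ** (1.0 / 3.0)
    )
    return n_g_per_s * 1e6


def equilibrated_transfer(
    params: TransportParameters, resistance: float, dP: float
) -> float:
    """Equilibrated-outflow transfer N_flow,2 = c_mat*B*dP/R in ug/s."""
    if resistance <= 0:
        raise ValueError("resistance must be positive")
    if dP < 0:
        raise ValueError("dP must be nonnegative")
    return params.c_mat * params.B * dP / resistance * 1e6


def annular_diffusion_bound(
    params: TransportParameters, A: float, R0: float, d: float
) -> float:
    """Diffusion-limited upper bound N_max = D*A*c_mat/(R0*ln(1+d/R0)) in ug/s.

    Models the villous tissue as a concentric annulus of thickness d with
    the outer surface held at c_mat and a perfectly absorbing capillary.
    """
    if A <= 0 or R0 <= 0:
        raise ValueError("A and R0 must be positive")
    if d <= 0:
        raise ValueError(
            "d must be positive: with d = 0 the capillary touches the villous "
            "surface and the annular bound diverges"
        )
    return params.D * A * params.c_mat / (R0 * math.log1p(d / R0)) * 1e6


def regression_flow(
    params: TransportParameters, L: float, resistance: float, dP: float
) -> tuple[float, float, float]:
    """Regression interpolant between the two flow-limited asymptotes.

    Returns ``(N_flow, K1, K2)`` in ug/s units, where
    N_flow = K1*K2*dP / (K2 + K1*dP^{2/3}), K1 = c_mat*B/R and
    K2 = alpha*c_mat*(D^2*B*L^2/R)^{1/3}; N_flow ~ K1*dP as dP -> 0 and
    ~ K2*dP^{1/3} as dP -> inf.
    """
    if L <= 0 or resistance <= 0:
        raise ValueError("L and resistance must be positive")
    if dP < 0:
        raise ValueError("dP must be nonnegative")
    K1 = params.c_mat * params.B / resistance * 1e6
    K2 = (
        LEVEQUE_PREFACTOR
        * params.c_mat
        * (params.D**2 * params.B * L**2 / resistance) ** (1.0 / 3.0)
        * 1e6
    )
    if dP == 0.0:
        return 0.0, K1, K2
    n = K1 * K2 * dP / (K2 + K1 * dP ** (2.0 / 3.0))
    return n, K1, K2


def villous_corrected_transfer(N_flow: float, N_max: float) -> tuple[float, float]:
    """Cap a flow-limited rate by the villous diffusion bound.

    Returns ``(N, c_inner/c_mat)`` with N = N_flow/(1 + N_flow/N_max) and
    c_inner/c_mat = 1 - N/N_max, the oxygen depletion at the capillary
    surface caused by the finite diffusive capacity of the villous tissue.
    """
    if N_flow < 0:
        raise ValueError("N_flow must be nonnegative")
    if N_max <= 0:
        raise ValueError("N_max must be positive")
    n = N_flow / (1.0 + N_flow / N_max)
    return n, 1.0 - n / N_max


def classify_regime(
    params: TransportParameters,
    u0: float,
    R0: float,
    d: float,
    L_path: float,
    N_flow: float,
    N_max: float,
    threshold: float = 10.0,
) -> Regime:
    """Label the transfer regime by the scaling inequalities.

    The asymptotic regimes are separated by order-of-magnitude inequalities;
    ``threshold`` operationalizes "much greater than".  Boundary cases are
    reported as ``crossover`` rather than guessed.
    """
    if threshold < 1:
        raise ValueError("threshold must be >= 1")
    pe = effective_peclet(params, u0, R0)
    ratio = L_path * R0 / (d + R0) ** 2
    if N_flow >= threshold * N_max:
        return "diffusion_limited"
    if pe * threshold <= ratio:
        return "flow_limited_equilibrated"
    if pe >= threshold * ratio and N_flow * threshold <= N_max:
        return "flow_limited_leveque"
    return "crossover"


def sensitivity_factor(
    k: float,
    mode: Literal["uniform", "radius_only"],
    regime: Literal["low_Pe", "high_Pe"],
) -> float:
    """Multiplicative change of N under geometric rescaling by factor k.

    A uniform expansion of every length by k changes N by k^3 at low
    Péclet (equilibrated, via Q = dP/R ∝ R0^4/L) and k^{5/3} at high
    Péclet (Lévêque, via (L^2/R)^{1/3}); rescaling the radius alone gives
    k^4 and k^{4/3} respectively.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    exponents = {
        ("uniform", "low_Pe"): 3.0,
        ("uniform", "high_Pe"): 5.0 / 3.0,
        ("radius_only", "low_Pe"): 4.0,
        ("radius_only", "high_Pe"): 4.0 / 3.0,
    }
    try:
        return k ** exponents[(mode, regime)]
    except KeyError:
        raise ValueError(f"unknown mode/regime combination ({mode!r}, {regime!r})")


# ---------------------------------------------------------------------------
# pipeline
# ---------------------------------------------------------------------------

def predict_transfer(
    summary: CapillarySummary,
    params: TransportParameters,
    dP: float,
    threshold: float = 10.0,
    use_numeric_nmax: bool = True,
) -> TransferPrediction:
    """Full reduced-order prediction for one capillary at one pressure drop.

    ``use_numeric_nmax`` prefers an externally computed (e.g. 3D numerical)
    N_max stored on the summary over the annular closed form, when present.
    """
    R0 = summary.radius
    R = summary.resistance(params.mu)
    n1 = leveque_transfer(params, summary.L, R, dP)
    n2 = equilibrated_transfer(params, R, dP)
    n_reg, K1, K2 = regression_flow(params, summary.L, R, dP)
    if use_numeric_nmax and summary.N_max_numeric is not None:
        n_max = summary.N_max_numeric
    else:
        n_max = annular_diffusion_bound(params, summary.A, R0, summary.d)
    n_corr, c_inner = villous_corrected_transfer(n_reg, n_max)
    # velocity scale from the flow rate: u0 = Q/(pi R0^2) with Q = dP/R
    u0 = dP / R / (math.pi * R0**2)
    regime = classify_regime(
        params, u0, R0, summary.d, summary.L_path, n_reg, n_max, threshold
    )
    return TransferPrediction(
        label=summary.label,
        dP=dP,
        N_flow_1=n1,
        N_flow_2=n2,
        N_flow_regression=n_reg,
        N_max=n_max,
        N_corrected=n_corr,
        N_ratio=n_corr / n_reg if n_reg > 0 else 1.0,
        c_inner_fraction=c_inner,
        K1=K1,
        K2=K2,
        regime=regime,
        Pe_eff=effective_peclet(params, u0, R0),
    )


_CSV_COLUMNS = [
    "label", "L", "L_path", "V_cap", "R0", "d", "A", "R_resistance", "N_max_numeric",
]


def read_summaries(path: str | Path) -> list[CapillarySummary]:
    """Read a CapillarySummary table from CSV (header row, NaN = missing)."""
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for col in _CSV_COLUMNS:
            if col in df.columns and not pd.isna(row[col]):
                kwargs[col] = row[col] if col == "label" else float(row[col])
        out.append(CapillarySummary(**kwargs))
    return out


def write_summaries(summaries: list[CapillarySummary], path: str | Path) -> None:
    rows = []
    for s in summaries:
        rec = asdict(s)
        rows.append({col: rec.get(col) for col in _CSV_COLUMNS})
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)
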