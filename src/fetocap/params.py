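"""Physical transport parameters and the oxygen–hemoglobin advection enhancement.

Oxygen in fetal blood travels both dissolved in plasma and bound to
hemoglobin.  Over the physiological range of fetal partial pressures
(0–60 mmHg) the dissociation curve S(P_O2) is well approximated by a
straight line through the origin with slope K, which turns the coupled
dissolved/bound transport problem into a single advection–diffusion
equation with the advective term amplified by a constant factor

    B = 1 + c_max * K * k_hn / rho_bl,

where c_max is the oxygen content of fully saturated blood, k_hn the
Henry's-law coefficient and rho_bl the blood density.  The effective
Péclet number Pe_eff = B * u0 * R0 / D then measures hemoglobin-enhanced
advection against plasma diffusion.

Internal unit system: micrometres, seconds, pascals, grams.  Converters
live at the I/O boundary (see :func:`TransportParameters.from_dict`).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "O2_MOLAR_MASS_G_PER_MOL",
    "TransportParameters",
    "advection_enhancement",
    "effective_peclet",
    "hill_saturation",
    "linearize_dissociation",
]

#: Molar mass of O2, used to convert mol/m^3 <-> g/m^3 concentrations.
O2_MOLAR_MASS_G_PER_MOL = 32.0

#: g/m^3 -> g/um^3 (1 m^3 = 1e18 um^3).
_G_PER_M3_TO_G_PER_UM3 = 1e-18


def advection_enhancement(c_max: float, K: float, k_hn: float, rho_bl: float) -> float:
    """Enhancement factor B = 1 + c_max*K*k_hn/rho_bl.

    Parameters
    ----------
    c_max : oxygen content of fetal blood at full saturation.
    K : slope of the linearized dissociation curve (mmHg^-1); K >= 0.
    k_hn : Henry's-law coefficient.
    rho_bl : density of blood; must be positive.

    Units of ``c_max``, ``k_hn`` and ``rho_bl`` must be mutually consistent
    so that the product is dimensionless.
    """
    if rho_bl <= 0:
        raise ValueError(f"rho_bl must be positive, got {rho_bl}")
    if c_max <= 0 or k_hn <= 0:
        raise ValueError("c_max and k_hn must be positive")
    if K < 0:
        raise ValueError(f"K must be nonnegative, got {K}")
    return 1.0 + c_max * K * k_hn / rho_bl


def linearize_dissociation(
    saturation_samples: Sequence[tuple[float, float]], p_max: float = 60.0
) -> float:
    """Least-squares slope K of S ~ K*P_O2 through the origin.

    Fits the dissociation samples ``(P_O2 in mmHg, S in [0, 1])`` restricted
    to P_O2 <= p_max with the constraint S(0) = 0, giving the closed form
    K = sum(P*S) / sum(P^2).

    Raises
    ------
    ValueError
        If no samples fall in [0, p_max] or all sample pressures are zero
        (degenerate fit).
    """
    if p_max <= 0:
        raise ValueError(f"p_max must be positive, got {p_max}")
    pts = [(float(p), float(s)) for p, s in saturation_samples if 0.0 <= p <= p_max]
    if not pts:
        raise ValueError("no dissociation samples in [0, p_max]")
    p = np.array([q[0] for q in pts])
    s = np.array([q[1] for q in pts])
    denom = float(np.dot(p, p))
    if denom == 0.0:
        raise ValueError("degenerate fit: all sample pressures are zero")
    return float(np.dot(p, s) / denom)


def hill_saturation(p50_mmHg: float = 19.0, n: float = 2.7) -> Callable[[float], float]:
    """A Hill-type saturation law S(P) = P^n / (P50^n + P^n).

    Convenience factory for nonlinear-dissociation runs and testing; the
    defaults give a curve broadly representative of fetal blood.  Accepts
    scalars or numpy arrays.
    """
    if p50_mmHg <= 0 or n <= 0:
        raise ValueError("p50 and Hill exponent must be positive")

    def law(p):
        p = np.maximum(np.asarray(p, dtype=float), 0.0)
        out = p**n / (p50_mmHg**n + p**n)
        return float(out) if out.ndim == 0 else out

    return law


@dataclass
class TransportParameters:
    """Oxygen transport parameters in internal units (um, s, Pa, g).

    Attributes
    ----------
    D : diffusion coefficient of oxygen in plasma (um^2/s).
    mu : dynamic viscosity of plasma (Pa s).
    c_mat : dissolved-oxygen concentration in the intervillous (maternal)
        space (g/um^3).
    B : advection enhancement factor (dimensionless, >= 1).
    K : slope of the linearized dissociation curve (mmHg^-1).
    c_max, k_hn, rho_bl : optional constituents of B; if all three are
        supplied together with K, B is checked (or computed if left None)
        from 1 + c_max*K*k_hn/rho_bl.
    saturation_law : optional callable P_O2 (mmHg) -> S in [0, 1] for
        nonlinear-dissociation runs; must be nondecreasing on [0, 60].
    """

    D: float = 1.7e3
    mu: float = 1.0e-3
    c_mat: float = 2.24 * _G_PER_M3_TO_G_PER_UM3
    B: float = 141.0
    K: float = 0.019
    c_max: float | None = None
    k_hn: float | None = None
    rho_bl: float | None = None
    saturation_law: Callable[[float], float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.D <= 0:
            raise ValueError(f"D must be positive, got {self.D}")
        if self.mu <= 0:
            raise ValueError(f"mu must be positive, got {self.mu}")
        if self.c_mat < 0:
            raise ValueError(f"c_mat must be nonnegative, got {self.c_mat}")
        constituents = (self.c_max, self.k_hn, self.rho_bl)
        if all(v is not None for v in constituents):
            b = advection_enhancement(self.c_max, self.K, self.k_hn, self.rho_bl)
            if self.B is None:
                self.B = b
            elif not math.isclose(self.B, b, rel_tol=1e-12):
                raise ValueError(
                    f"B={self.B} inconsistent with constituents (1 + c_max*K*k_hn/rho_bl = {b})"
                )
        if self.B < 1:
            raise ValueError(f"B must be >= 1, got {self.B}")
        if self.saturation_law is not None:
            self._check_saturation_law()

    def _check_saturation_law(self) -> None:
        p = np.linspace(0.0, 60.0, 121)
        s = np.asarray([self.saturation_law(x) for x in p], dtype=float)
        if abs(s[0]) > 1e-9:
            raise ValueError(f"saturation_law(0) = {s[0]}, expected 0")
        if np.any(np.diff(s) < -1e-12):
            raise ValueError("saturation_law must be nondecreasing on [0, 60] mmHg")

    # ---- I/O -----------------------------------------------------------
    @classmethod
    def from_dict(cls, cfg: dict) -> "TransportParameters":
        """Build from a flat key-value config.

        Recognized keys: ``D_um2_per_s``, ``mu_Pa_s``, ``c_mat_mol_per_m3``
        or ``c_mat_g_per_m3`` (exactly one), ``B``, ``K_per_mmHg``.
        Missing keys fall back to the shipped defaults.
        """
        kwargs: dict = {}
        if "D_um2_per_s" in cfg:
            kwargs["D"] = float(cfg["D_um2_per_s"])
        if "mu_Pa_s" in cfg:
            kwargs["mu"] = float(cfg["mu_Pa_s"])
        if "c_mat_mol_per_m3" in cfg and "c_mat_g_per_m3" in cfg:
            raise ValueError("give c_mat in mol/m3 or g/m3, not both")
        if "c_mat_mol_per_m3" in cfg:
            g_per_m3 = float(cfg["c_mat_mol_per_m3"]) * O2_MOLAR_MASS_G_PER_MOL
            kwargs["c_mat"] = g_per_m3 * _G_PER_M3_TO_G_PER_UM3
        elif "c_mat_g_per_m3" in cfg:
            kwargs["c_mat"] = float(cfg["c_mat_g_per_m3"]) * _G_PER_M3_TO_G_PER_UM3
        if "B" in cfg:
            kwargs["B"] = float(cfg["B"])
        if "K_per_mmHg" in cfg:
            kwargs["K"] = float(cfg["K_per_mmHg"])
        return cls(**kwargs)

    @classmethod
    def from_json(cls, path: str | Path) -> "TransportParameters":
        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(json.load(fh))

    def to_dict(self) -> dict:
        return {
            "D_um2_per_s": self.D,
            "mu_Pa_s": self.mu,
            "c_mat_g_per_m3": self.c_mat / _G_PER_M3_TO_G_PER_UM3,
            "B": self.B,
            "K_per_mmHg": self.K,
        }


def effective_peclet(params: TransportParameters, u0: float, R0: float) -> float:
    """Effective Péclet number Pe_eff = B*u0*R0/D.

    ``u0`` is a characteristic axial velocity (um/s, >= 0) and ``R0`` the
    capillary radius (um, > 0).
    """
    if u0 < 0:
        raise ValueError(f"u0 must be nonnegative, got {u0}")
    if R0 <= 0:
        raise ValueError(f"R0 must be positive, got {R0}")
    return params.B * u0 * R0 / params.D
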