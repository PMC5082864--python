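"""Fourier parameterization of an axisymmetric capillary dilation.

Inside a window of length ``lam`` the wall radius is a truncated Fourier
series in the local coordinate zeta = z - z_start,

    R(zeta)/R0 = a0/2 + sum_k a_k cos(k*pi*zeta/lam)
                      + sum_k b_k sin(k*pi*zeta/lam),

subject to the four linear continuity/smoothness constraints

    R(0) = R(lam) = R0,   R'(0) = R'(lam) = 0,

so the wall joins the straight sections of radius R0 with a continuous
value and slope.  The constraints are enforced exactly by eliminating the
four low-order coefficients (a0, a1, b1, b2) in terms of the remaining
free ones.

Mid-plane symmetric shapes: cos(k*pi*zeta/lam) is symmetric about
zeta = lam/2 for even k and antisymmetric for odd k, while the sine terms
are symmetric for odd k.  The default ``strict_parity`` symmetry mode
therefore keeps only even-k cosines; the alternative ``odd_zero`` mode
zeroes all odd-k coefficients (cosines and sines) instead.  With strict
parity the n = 2 family has a single degree of freedom, the cosine bump

    R(zeta)/R0 = 1 + (R_max/R0 - 1) * (1 - cos(2*pi*zeta/lam)) / 2,

and n = 4 adds the k = 4 cosine as a second degree of freedom.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import minimize_scalar

__all__ = [
    "DilationShape",
    "apply_constraints",
    "bump_shape",
    "n_free_dof",
    "shape_extrema",
]

_SYMMETRY_MODES = ("strict_parity", "odd_zero")


@dataclass
class DilationShape:
    """A dilated axisymmetric tube of length L with an interior bump.

    ``a`` holds a_0..a_n, ``b`` holds b_1..b_n (index 0 of ``b`` is b_1).
    Outside [z_start, z_start+lam] the radius is the constant R0.
    """

    R0: float
    lam: float
    L: float
    n: int
    a: np.ndarray
    b: np.ndarray
    z_start: float | None = None
    symmetric: bool = False
    symmetry_mode: str = "strict_parity"
    r_min_fraction: float = 0.2

    def __post_init__(self) -> None:
        if self.R0 <= 0 or self.lam <= 0 or self.L <= 0:
            raise ValueError("R0, lam and L must be positive")
        if self.lam > self.L:
            raise ValueError(f"dilation length {self.lam} exceeds tube length {self.L}")
        if self.n < 2:
            raise ValueError("truncation order n must be >= 2")
        if self.symmetry_mode not in _SYMMETRY_MODES:
            raise ValueError(f"symmetry_mode must be one of {_SYMMETRY_MODES}")
        if self.z_start is None:
            self.z_start = 0.5 * (self.L - self.lam)
        if not (0.0 <= self.z_start <= self.L - self.lam + 1e-12):
            raise ValueError("dilation window must lie inside [0, L]")
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != (self.n + 1,) or self.b.shape != (self.n,):
            raise ValueError("a must have n+1 entries (a_0..a_n), b must have n (b_1..b_n)")
        res = self.constraint_residuals()
        if np.max(np.abs(res)) > 1e-10:
            raise ValueError(f"continuity/smoothness constraint residuals too large: {res}")

    # -- evaluation ------------------------------------------------------
    def radius(self, z):
        """Wall radius R(z) in um; accepts scalars or arrays, 0 <= z <= L."""
        z = np.asarray(z, dtype=float)
        if np.any(z < -1e-9) or np.any(z > self.L + 1e-9):
            raise ValueError("z outside [0, L]")
        zeta = z - self.z_start
        inside = (zeta >= 0.0) & (zeta <= self.lam)
        r = np.full(z.shape, self.R0)
        if np.any(inside):
            x = np.pi * zeta[inside] / self.lam
            k = np.arange(1, self.n + 1)
            series = self.a[0] / 2.0
            series = series + np.cos(np.outer(x, k)) @ self.a[1:]
            series = series + np.sin(np.outer(x, k)) @ self.b
            r[inside] = self.R0 * series
        return float(r) if r.ndim == 0 else r

    def constraint_residuals(self) -> np.ndarray:
        """Residuals of [R(0)-R0, R(lam)-R0, R'(0), R'(lam)] in units of R0."""
        k = np.arange(1, self.n + 1)
        sgn = (-1.0) ** k
        return np.array(
            [
                self.a[0] / 2.0 + self.a[1:].sum() - 1.0,
                self.a[0] / 2.0 + (sgn * self.a[1:]).sum() - 1.0,
                (k * self.b).sum(),
                (k * sgn * self.b).sum(),
            ]
        )

    # -- serialization ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "R0_um": self.R0,
            "lambda_um": self.lam,
            "L_um": self.L,
            "z_start_um": self.z_start,
            "n": self.n,
            "a": list(self.a),
            "b": list(self.b),
            "symmetric": self.symmetric,
            "symmetry_mode": self.symmetry_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "DilationShape":
        return cls(
            R0=d["R0_um"],
            lam=d["lambda_um"],
            L=d["L_um"],
            z_start=d.get("z_start_um"),
            n=d["n"],
            a=np.asarray(d["a"], dtype=float),
            b=np.asarray(d["b"], dtype=float),
            symmetric=d.get("symmetric", False),
            symmetry_mode=d.get("symmetry_mode", "strict_parity"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1), encoding="utf-8")

    @classmethod
    def from_json(cls, path: str | Path) -> "DilationShape":
        return cls.from_dict(json.loads(Path(path).read_text(encoding="utf-8")))

    def export_profile_csv(self, path: str | Path, n_points: int = 200) -> None:
        z = np.linspace(0.0, self.L, n_points)
        r = self.radius(z)
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("z_um,R_um\n")
            for zi, ri in zip(z, r):
                fh.write(f"{zi:.10g},{ri:.10g}\n")


def n_free_dof(n: int, symmetric: bool, symmetry_mode: str = "strict_parity") -> int:
    """Number of free parameters after constraints and symmetry zeroing."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if not symmetric:
        # (n+1) cosines + n sines - 4 eliminated (a0, a1, b1, b2)
        return 2 * n - 3
    if symmetry_mode == "strict_parity":
        # a0 and even-k cosines, one constraint eliminates a0
        return n // 2
    # odd_zero: a0, even cosines, even sines; eliminate a0 and b2
    return n // 2 + max(n // 2 - 1, 0)


def apply_constraints(
    free_params,
    n: int,
    symmetric: bool = False,
    *,
    R0: float = 1.0,
    lam: float = 1.0,
    L: float | None = None,
    z_start: float | None = None,
    symmetry_mode: str = "strict_parity",
) -> DilationShape:
    """Build a constraint-satisfying shape from free Fourier coefficients.

    The four linear constraints are solved for the designated elimination
    set; the remaining coefficients are taken verbatim from ``free_params``
    (dimensionless, in units of R0).

    Free-parameter layout:

    * asymmetric: ``[a_2, ..., a_n, b_3, ..., b_n]`` (eliminated: a0, a1,
      b1, b2);
    * symmetric, ``strict_parity``: ``[a_2, a_4, ..., a_{2*(n//2)}]``
      (eliminated: a0; all other coefficients zero);
    * symmetric, ``odd_zero``: ``[a_2, a_4, ...]`` then ``[b_4, b_6, ...]``
      (eliminated: a0 and b_2; odd-k coefficients zero).
    """
    free = np.atleast_1d(np.asarray(free_params, dtype=float))
    expected = n_free_dof(n, symmetric, symmetry_mode)
    if free.shape != (expected,):
        raise ValueError(
            f"expected {expected} free parameters for n={n}, symmetric={symmetric}, "
            f"mode={symmetry_mode}; got {free.shape[0]}"
        )
    a = np.zeros(n + 1)
    b = np.zeros(n)
    k = np.arange(1, n + 1)
    if not symmetric:
        a[2:] = free[: n - 1]
        if n >= 3:
            b[2:] = free[n - 1:]  # b_3..b_n
        # constraints: sum over odd k of a_k = 0 -> a1; a0 from R(0)=1
        odd = k % 2 == 1
        a1 = -np.sum(a[1:][odd & (k > 1)])
        a[1] = a1
        a[0] = 2.0 * (1.0 - a[1:].sum())
        # sum over odd k of k*b_k = 0 -> b1; sum over even k of k*b_k = 0 -> b2
        b[0] = -np.sum((k * b)[odd & (k > 1)])
        even = ~odd
        b[1] = -np.sum((k * b)[even & (k > 2)]) / 2.0
    elif symmetry_mode == "strict_parity":
        even_idx = np.arange(2, n + 1, 2)
        a[even_idx] = free
        a[0] = 2.0 * (1.0 - a[1:].sum())
    else:  # odd_zero
        even_idx = np.arange(2, n + 1, 2)
        n_cos = len(even_idx)
        a[even_idx] = free[:n_cos]
        sine_idx = np.arange(4, n + 1, 2)  # b_4, b_6, ... (b_2 eliminated)
        b[sine_idx - 1] = free[n_cos:]
        b[1] = -np.sum(sine_idx * b[sine_idx - 1]) / 2.0
        a[0] = 2.0 * (1.0 - a[1:].sum())
    shape = DilationShape(
        R0=R0,
        lam=lam,
        L=L if L is not None else lam,
        z_start=z_start,
        n=n,
        a=a,
        b=b,
        symmetric=symmetric,
        symmetry_mode=symmetry_mode,
    )
    return shape


def bump_shape(
    R0: float, R_max: float, lam: float, L: float, z_start: float | None = None
) -> DilationShape:
    """The one-degree-of-freedom symmetric cosine bump.

    R(zeta)/R0 = 1 + (R_max/R0 - 1)*(1 - cos(2*pi*zeta/lam))/2 — the
    lowest-order symmetric series member satisfying the wall constraints,
    with maximum radius R_max at the window midpoint.
    """
    if R_max <= 0:
        raise ValueError("R_max must be positive")
    a2 = -0.5 * (R_max / R0 - 1.0)
    return apply_constraints([a2], n=2, symmetric=True, R0=R0, lam=lam, L=L, z_start=z_start)


def shape_extrema(shape: DilationShape, n_grid: int = 4001) -> tuple[float, float, float]:
    """Global (R_min, R_max, z_at_max) of R over the dilation window.

    Dense sampling over the window followed by local golden-section
    refinement around the grid extrema; accurate to ~1e-6*R0.
    """
    z0, z1 = shape.z_start, shape.z_start + shape.lam
    z = np.linspace(z0, z1, n_grid)
    r = shape.radius(z)

    def refine(idx: int, sign: float) -> tuple[float, float]:
        lo = z[max(idx - 1, 0)]
        hi = z[min(idx + 1, n_grid - 1)]
        if hi - lo < 1e-14:
            return z[idx], r[idx]
        res = minimize_scalar(
            lambda zz: sign * shape.radius(float(np.clip(zz, z0, z1))),
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-10 * shape.lam},
        )
        return float(res.x), float(sign * res.fun)

    z_max, r_max = refine(int(np.argmax(r)), -1.0)
    _, r_min = refine(int(np.argmin(r)), 1.0)
    # the straight sections outside the window have radius R0
    r_min = min(r_min, shape.R0)
    r_max = max(r_max, shape.R0)
    return r_min, r_max, z_max
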