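"""Shape optimization of a capillary dilation at fixed pressure drop.

The oxygen transfer rate N of an axisymmetric capillary with a localized
dilation is maximized over the free Fourier coefficients of the wall
shape, at a pressure drop calibrated to give a prescribed centreline
velocity in the undilated tube.  Two competing effects produce an
interior optimum in the maximum radius: widening lowers the resistance
(raising the flow rate at fixed pressure drop) and adds transfer area,
but slows the local flow over the oxygenated wall, thinning the supply
of fresh blood to the boundary layer.

Each objective evaluation is a full finite-element solve (mesh, Stokes,
transport); gradients are central finite differences of the objective,
and the constrained local maximization uses SLSQP (a sequential
quadratic programming method) from at least ten random feasible starts.
Feasibility (wall extrema within prescribed bounds, no occlusion) is
enforced by construction and by explicit inequality constraints, not by
penalties.  The dimension of the search space is raised by continuation:
each degree-of-freedom stage seeds one start from the previous optimum.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize

from .params import TransportParameters
from .shape import DilationShape, apply_constraints, n_free_dof, shape_extrema
from .axisym import build_mesh, calibrate_pressure, solve_oxygen, solve_stokes
from .axisym.solver import SolverError

__all__ = [
    "DilationObjective",
    "OptimizationResult",
    "StartRecord",
    "dof_continuation",
    "optimize",
    "sweep_1dof",
]


@dataclass
class StartRecord:
    x0: np.ndarray
    x_opt: np.ndarray
    N: float
    converged: bool
    message: str = ""


@dataclass
class OptimizationResult:
    best_shape: DilationShape
    N_opt: float
    N_straight: float
    n_dof: int
    seed: int
    starts: list[StartRecord] = field(default_factory=list)
    N_refined: float | None = None
    refinement_rel_diff: float | None = None

    @property
    def enhancement_percent(self) -> float:
        return 100.0 * (self.N_opt / self.N_straight - 1.0)

    def to_dict(self) -> dict:
        return {
            "best_shape": self.best_shape.to_dict(),
            "N_opt_ug_per_s": self.N_opt,
            "N_straight_ug_per_s": self.N_straight,
            "enhancement_percent": self.enhancement_percent,
            "n_dof": self.n_dof,
            "seed": self.seed,
            "N_refined_ug_per_s": self.N_refined,
            "refinement_rel_diff": self.refinement_rel_diff,
            "starts": [
                {
                    "x0": list(s.x0),
                    "x_opt": list(s.x_opt),
                    "N_ug_per_s": s.N,
                    "converged": s.converged,
                    "message": s.message,
                }
                for s in self.starts
            ],
        }


class DilationObjective:
    """Memoized FEM evaluation of N over the free shape coefficients.

    Fixes the capillary (R0, lam, L), the transport parameters, the
    pressure drop and the mesh settings; ``__call__`` maps a free
    coefficient vector to the oxygen transfer rate in ug/s.  During the
    search the discrete-maximum-principle check is relaxed (the final
    optimum is re-verified at the strict default), and solver failures
    at extreme iterates return -inf rather than raising.
    """

    def __init__(
        self,
        R0: float,
        lam: float,
        L: float,
        params: TransportParameters,
        dP: float,
        n: int,
        symmetric: bool = True,
        resolution: int = 13,
        extrema_bounds: tuple[float, float] = (0.5, 2.5),
        search_max_principle_tol: float = 5e-3,
    ) -> None:
        self.R0, self.lam, self.L = R0, lam, L
        self.params, self.dP = params, dP
        self.n, self.symmetric = n, symmetric
        self.resolution = resolution
        self.extrema_bounds = extrema_bounds
        self.search_tol = search_max_principle_tol
        self.n_dof = n_free_dof(n, symmetric)
        self._cache: dict[tuple, float] = {}
        self.n_evaluations = 0

    def shape(self, x) -> DilationShape:
        return apply_constraints(
            np.asarray(x, dtype=float),
            n=self.n,
            symmetric=self.symmetric,
            R0=self.R0,
            lam=self.lam,
            L=self.L,
        )

    def extrema(self, x) -> tuple[float, float]:
        r_min, r_max, _ = shape_extrema(self.shape(x))
        return r_min, r_max

    def solve(self, x, resolution: int | None = None, strict: bool = True):
        shape = self.shape(x)
        mesh = build_mesh(shape, resolution=resolution or self.resolution)
        flow = solve_stokes(mesh, self.params.mu, self.dP)
        return solve_oxygen(
            mesh,
            flow,
            self.params,
            max_principle_tol=1e-3 if strict else self.search_tol,
        )

    def __call__(self, x) -> float:
        key = tuple(np.round(np.asarray(x, dtype=float), 12))
        if key not in self._cache:
            self.n_evaluations += 1
            try:
                self._cache[key] = self.solve(x, strict=False).N
            except (SolverError, ValueError):
                self._cache[key] = -math.inf
        return self._cache[key]

    def feasible(self, x) -> bool:
        lo, hi = self.extrema_bounds
        r_min, r_max = self.extrema(x)
        return r_min >= lo * self.R0 - 1e-9 and r_max <= hi * self.R0 + 1e-9


def _project_to_feasible(obj: DilationObjective, x: np.ndarray) -> np.ndarray:
    """Shrink toward the straight tube until the extrema bounds hold.

    R(z) - R0 is linear in the free coefficients, so scaling them scales
    the deviation; the straight tube (x = 0) is always feasible.
    """
    x = np.asarray(x, dtype=float)
    for _ in range(60):
        if obj.feasible(x):
            return x
        x = 0.85 * x
    return np.zeros_like(x)


def _local_maximize(obj: DilationObjective, x0: np.ndarray, fd_step: float = 1e-3,
                    maxiter: int = 40) -> StartRecord:
    scale = max(float(np.max(np.abs(x0))), 0.25)
    n_straight_proxy = obj(np.zeros_like(x0))

    def fun(x):
        n = obj(x)
        if not math.isfinite(n):
            return 10.0  # infeasible solver state: strongly penalized
        return -n / n_straight_proxy

    def jac(x):
        g = np.empty_like(x)
        h = fd_step * scale
        for i in range(len(x)):
            e = np.zeros_like(x)
            e[i] = h
            g[i] = (fun(x + e) - fun(x - e)) / (2 * h)
        return g

    lo, hi = obj.extrema_bounds
    cons = [
        {"type": "ineq", "fun": lambda x: obj.extrema(x)[0] / obj.R0 - lo},
        {"type": "ineq", "fun": lambda x: hi - obj.extrema(x)[1] / obj.R0},
    ]
    res = minimize(
        fun,
        x0,
        jac=jac,
        method="SLSQP",
        constraints=cons,
        options={"maxiter": maxiter, "ftol": 1e-6},
    )
    x_opt = _project_to_feasible(obj, res.x)
    return StartRecord(
        x0=np.asarray(x0, dtype=float),
        x_opt=x_opt,
        N=obj(x_opt),
        converged=bool(res.success),
        message=str(res.message),
    )


def optimize(
    n_dof: int,
    R0: float,
    lam: float,
    L: float,
    params: TransportParameters | None = None,
    dP: float | None = None,
    u_centreline: float = 300.0,
    multistart: int = 10,
    seed: int = 0,
    extrema_bounds: tuple[float, float] = (0.5, 2.5),
    resolution: int = 13,
    symmetric: bool = True,
    extra_starts: list[np.ndarray] | None = None,
    refine_check: bool = True,
) -> OptimizationResult:
    """Maximize N over a symmetric shape family with ``n_dof`` free coefficients.

    ``dP`` defaults to the pressure drop giving ``u_centreline`` on the
    centreline of the undilated tube.  At least ten random feasible
    starts are run (plus any ``extra_starts``, e.g. from continuation);
    the best converged local maximum wins.  The returned optimum is
    re-evaluated at one mesh-refinement level as an accuracy diagnostic.
    Deterministic for a given seed and configuration.
    """
    if n_dof < 1:
        raise ValueError("n_dof must be >= 1")
    if multistart < 1:
        raise ValueError("multistart must be >= 1")
    if params is None:
        params = TransportParameters()
    if dP is None:
        dP = calibrate_pressure(R0, L, params.mu, u_centreline)
    n = 2 * n_dof if symmetric else max(2, (n_dof + 3 + 1) // 2)
    if not symmetric and n_free_dof(n, False) != n_dof:
        raise ValueError(
            f"asymmetric families have 2n-3 free coefficients; n_dof={n_dof} unavailable"
        )
    obj = DilationObjective(
        R0, lam, L, params, dP, n=n, symmetric=symmetric,
        resolution=resolution, extrema_bounds=extrema_bounds,
    )
    rng = np.random.default_rng(seed)
    starts: list[np.ndarray] = [np.asarray(x, dtype=float) for x in (extra_starts or [])]
    while len(starts) < multistart:
        # amplitude range chosen so the 1-DOF leading coefficient spans the
        # full non-occluding dilation/constriction range
        x = rng.uniform(-0.75, 0.25, size=obj.n_dof)
        starts.append(_project_to_feasible(obj, x))

    records = [_local_maximize(obj, x0) for x0 in starts]
    # continuation seed points are themselves candidates: the nested
    # families then give nondecreasing optima by construction
    for x in extra_starts or []:
        x = np.asarray(x, dtype=float)
        records.append(
            StartRecord(x0=x, x_opt=x, N=obj(x), converged=True, message="seed point")
        )
    converged = [r for r in records if r.converged and math.isfinite(r.N)]
    pool = converged if converged else [r for r in records if math.isfinite(r.N)]
    if not pool:
        raise SolverError(
            "no optimization start produced a valid solution; "
            f"diagnostics: {[r.message for r in records]}"
        )
    best = max(pool, key=lambda r: r.N)
    n_straight = obj(np.zeros(obj.n_dof))
    result = OptimizationResult(
        best_shape=obj.shape(best.x_opt),
        N_opt=best.N,
        N_straight=n_straight,
        n_dof=n_dof,
        seed=seed,
        starts=records,
    )
    if refine_check:
        refined = obj.solve(best.x_opt, resolution=resolution + 4, strict=False)
        result.N_refined = refined.N
        result.refinement_rel_diff = abs(refined.N - best.N) / abs(refined.N)
    return result


def sweep_1dof(
    R0: float,
    lam: float,
    L: float,
    params: TransportParameters | None = None,
    dP: float | None = None,
    R_max_grid=None,
    u_centreline: float = 300.0,
    resolution: int = 13,
    extrema_bounds: tuple[float, float] = (0.5, 2.5),
) -> dict:
    """Enhancement curve N(R_max) for the 1-DOF cosine-bump family.

    One FEM solve per grid point; the optimizer's result can be validated
    against the argmax of this curve.
    """
    if params is None:
        params = TransportParameters()
    if dP is None:
        dP = calibrate_pressure(R0, L, params.mu, u_centreline)
    if R_max_grid is None:
        R_max_grid = R0 * np.linspace(1.0, extrema_bounds[1], 13)
    obj = DilationObjective(
        R0, lam, L, params, dP, n=2, symmetric=True,
        resolution=resolution, extrema_bounds=extrema_bounds,
    )
    r_grid = np.asarray(R_max_grid, dtype=float)
    lo, hi = extrema_bounds
    if np.any(r_grid < lo * R0 - 1e-9) or np.any(r_grid > hi * R0 + 1e-9):
        raise ValueError("R_max grid outside the extrema bounds")
    n_straight = obj(np.zeros(1))
    ns, enh = [], []
    for r_max in r_grid:
        x = np.array([-0.5 * (r_max / R0 - 1.0)])
        n = obj(x)
        ns.append(n)
        enh.append(100.0 * (n / n_straight - 1.0))
    i_best = int(np.nanargmax(ns))
    return {
        "R_max_um": r_grid,
        "N_ug_per_s": np.asarray(ns),
        "enhancement_percent": np.asarray(enh),
        "N_straight": n_straight,
        "argmax_R_max_um": float(r_grid[i_best]),
        "max_enhancement_percent": float(enh[i_best]),
        "dP_Pa": dP,
    }


def dof_continuation(
    max_dof: int,
    R0: float,
    lam: float,
    L: float,
    params: TransportParameters | None = None,
    dP: float | None = None,
    u_centreline: float = 300.0,
    multistart: int = 10,
    seed: int = 0,
    **kwargs,
) -> list[OptimizationResult]:
    """Optimize with successively more shape degrees of freedom.

    Stage d seeds one start from the stage d-1 optimum (zero-padded into
    the larger nested family), so the best transfer rate is nondecreasing
    across stages.
    """
    if max_dof < 1:
        raise ValueError("max_dof must be >= 1")
    results: list[OptimizationResult] = []
    prev_x: np.ndarray | None = None
    for d in range(1, max_dof + 1):
        extra = []
        if prev_x is not None:
            extra.append(np.concatenate([prev_x, np.zeros(d - len(prev_x))]))
        res = optimize(
            d, R0, lam, L, params=params, dP=dP, u_centreline=u_centreline,
            multistart=multistart, seed=seed + d, extra_starts=extra, **kwargs,
        )
        results.append(res)
        prev_x = _best_x(res)
    return results


def _best_x(result: OptimizationResult) -> np.ndarray:
    best = max(
        (r for r in result.starts if math.isfinite(r.N)), key=lambda r: r.N
    )
    return best.x_opt
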