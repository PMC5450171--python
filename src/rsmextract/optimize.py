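"""Characterization and optimization of fitted quadratic surfaces.

Single-response optima are located over a coded box (default the design
cube [-1, 1]^k) by a deterministic multi-start scheme: bounded L-BFGS-B
from every point of the 3^k corner/center lattice plus the unconstrained
stationary point when it lies inside the box.  Multi-response optima use
Derringer-Suich desirability: each response is mapped to [0, 1] by a
power-weighted ramp between two anchor values and the geometric mean of
the per-response desirabilities is maximized by the same scheme.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .model import QuadraticModel

__all__ = [
    "StationaryPoint",
    "OptimizationResult",
    "DesirabilitySpec",
    "predict",
    "stationary_point",
    "maximize_in_box",
    "desirability",
    "joint_optimize",
    "default_desirability_specs",
    "grid_export",
]


def predict(model: QuadraticModel, coded_point):
    """Evaluate ``model`` at a coded point (alias of ``model.predict``)."""
    return model.predict(coded_point)


@dataclass(frozen=True)
class StationaryPoint:
    """Unconstrained stationary point of a quadratic surface.

    ``kind`` is ``"maximum"``, ``"minimum"``, ``"saddle"`` or
    ``"degenerate"`` (singular Hessian; ``point`` is then None).
    """

    point: np.ndarray | None
    kind: str


def stationary_point(model: QuadraticModel, cond_limit: float = 1e10) -> StationaryPoint:
    """Solve the gradient system and classify by Hessian eigenvalue signs."""
    h = model.hessian()
    cond = np.linalg.cond(h)
    if not np.isfinite(cond) or cond > cond_limit:
        return StationaryPoint(point=None, kind="degenerate")
    x = np.linalg.solve(h, -model.linear)
    eig = np.linalg.eigvalsh(h)
    if np.all(eig < 0):
        kind = "maximum"
    elif np.all(eig > 0):
        kind = "minimum"
    else:
        kind = "saddle"
    return StationaryPoint(point=x, kind=kind)


@dataclass
class OptimizationResult:
    """Best point found by a box-constrained surface optimization."""

    coded_point: np.ndarray
    natural_point: dict[str, float]
    value: float
    boundary: list[bool]  # per factor: optimum on a box face
    stationary: StationaryPoint | None
    n_starts: int
    converged: bool
    response_values: dict[str, float] | None = None  # joint optimization only

    def to_dict(self) -> dict:
        return {
            "coded_point": [float(v) for v in self.coded_point],
            "natural_point": {k: float(v) for k, v in self.natural_point.items()},
            "value": float(self.value),
            "boundary": list(self.boundary),
            "stationary_kind": None if self.stationary is None else self.stationary.kind,
            "n_starts": self.n_starts,
            "converged": self.converged,
            "response_values": self.response_values,
        }


def _normalize_box(box, k: int) -> np.ndarray:
    if box is None:
        box = [(-1.0, 1.0)] * k
    box = np.asarray(box, dtype=float)
    if box.shape == (2,):
        box = np.tile(box, (k, 1))
    if box.shape != (k, 2) or np.any(box[:, 0] >= box[:, 1]):
        raise ValueError("box must give a non-empty (low, high) pair per factor")
    return box


def _lattice_starts(box: np.ndarray) -> np.ndarray:
    axes = [np.array([lo, 0.5 * (lo + hi), hi]) for lo, hi in box]
    return np.array(list(itertools.product(*axes)))


def _multistart_maximize(fun, grad, box: np.ndarray, extra_starts=()):
    """Deterministic multi-start bounded maximization of ``fun``."""
    starts = _lattice_starts(box)
    for s in extra_starts:
        starts = np.vstack([starts, s])
    best_x, best_v, ok = None, -np.inf, False
    for x0 in starts:
        res = minimize(
            lambda x: -fun(x),
            x0,
            jac=None if grad is None else (lambda x: -grad(x)),
            method="L-BFGS-B",
            bounds=list(map(tuple, box)),
        )
        v = -res.fun
        if v > best_v:
            best_x, best_v, ok = res.x, v, bool(res.success)
    # never report worse than the best start itself
    vals = [fun(x) for x in starts]
    i = int(np.argmax(vals))
    if vals[i] > best_v:
        best_x, best_v = starts[i], vals[i]
    return np.asarray(best_x), float(best_v), len(starts), ok


def maximize_in_box(model: QuadraticModel, box=None) -> OptimizationResult:
    """Maximize a fitted surface over a coded box.

    Starts are the 3^k lattice of box corners/edge-midpoints/center plus
    the unconstrained stationary point when it is interior, so the result
    is deterministic and never below the surface value at any start.
    """
    bx = _normalize_box(box, model.k)
    sp = stationary_point(model)
    extra = []
    if sp.point is not None and np.all(sp.point >= bx[:, 0]) and np.all(sp.point <= bx[:, 1]):
        extra.append(sp.point)
    x, v, n_starts, ok = _multistart_maximize(
        lambda p: model.predict(p), lambda p: model.gradient_at(p), bx, extra
    )
    x = np.clip(x, bx[:, 0], bx[:, 1])
    boundary = [bool(np.isclose(xi, lo) or np.isclose(xi, hi)) for xi, (lo, hi) in zip(x, bx)]
    natural = {f.name: f.decode(xi) for f, xi in zip(model.factors, x)}
    return OptimizationResult(
        coded_point=x,
        natural_point=natural,
        value=float(model.predict(x)),
        boundary=boundary,
        stationary=sp,
        n_starts=n_starts + len(extra),
        converged=ok,
    )


@dataclass(frozen=True)
class DesirabilitySpec:
    """Derringer-Suich desirability for one response.

    For ``goal="maximize"``: d = 0 at or below ``low``, 1 at or above
    ``high``, with d = ((y - low)/(high - low))**weight between.  For
    ``goal="minimize"`` the ramp is mirrored.  ``goal="target"`` ramps up
    to 1 at ``target`` and back down to 0 at ``high``.
    """

    goal: str  # "maximize" | "minimize" | "target"
    low: float
    high: float
    target: float | None = None
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.goal not in ("maximize", "minimize", "target"):
            raise ValueError(f"unknown goal {self.goal!r}")
        if not self.low < self.high:
            raise ValueError("anchors must satisfy low < high")
        if self.weight <= 0:
            raise ValueError("weight must be positive")
        if self.goal == "target" and not (self.target is not None and self.low < self.target < self.high):
            raise ValueError("target goal needs low < target < high")

    def d(self, y: float) -> float:
        lo, hi, w = self.low, self.high, self.weight
        if self.goal == "maximize":
            u = np.clip((y - lo) / (hi - lo), 0.0, 1.0)
            return float(u**w)
        if self.goal == "minimize":
            u = np.clip((hi - y) / (hi - lo), 0.0, 1.0)
            return float(u**w)
        t = self.target
        if y <= lo or y >= hi:
            return 0.0
        u = (y - lo) / (t - lo) if y <= t else (hi - y) / (hi - t)
        return float(u**w)


def desirability(values: dict[str, float], specs: dict[str, "DesirabilitySpec"]) -> float:
    """Overall desirability: geometric mean of per-response d values."""
    if set(values) != set(specs):
        raise ValueError("responses in values and specs do not match")
    ds = np.array([specs[name].d(values[name]) for name in specs])
    if np.any(ds == 0):
        return 0.0
    return float(np.exp(np.mean(np.log(ds))))


def default_desirability_specs(
    models: dict[str, QuadraticModel], box=None
) -> dict[str, DesirabilitySpec]:
    """Maximize-goal specs anchored at each surface's (min, max) over the box."""
    specs = {}
    for name, model in models.items():
        hi = maximize_in_box(model, box).value
        neg = QuadraticModel(
            response_name=model.response_name,
            factors=model.factors,
            intercept=-model.intercept,
            linear=-model.linear,
            interaction=-model.interaction,
            quadratic=-model.quadratic,
        )
        lo = -maximize_in_box(neg, box).value
        specs[name] = DesirabilitySpec(goal="maximize", low=lo, high=hi)
    return specs


def joint_optimize(
    models: dict[str, QuadraticModel],
    specs: dict[str, DesirabilitySpec] | None = None,
    box=None,
) -> OptimizationResult:
    """Maximize overall desirability over the box.

    All models must share the same factors.  When ``specs`` is omitted,
    per-response anchors default to each surface's own range over the box
    with weight 1 (so the joint optimum trades responses off evenly).
    """
    if not models:
        raise ValueError("need at least one model")
    ref = next(iter(models.values()))
    for m in models.values():
        if [f.name for f in m.factors] != [f.name for f in ref.factors]:
            raise ValueError("all models must share the same factor set")
    if specs is None:
        specs = default_desirability_specs(models, box)
    bx = _normalize_box(box, ref.k)

    def overall(x):
        return desirability({n: m.predict(x) for n, m in models.items()}, specs)

    extra = [
        sp.point
        for sp in (stationary_point(m) for m in models.values())
        if sp.point is not None
        and np.all(sp.point >= bx[:, 0])
        and np.all(sp.point <= bx[:, 1])
    ]
    x, v, n_starts, ok = _multistart_maximize(overall, None, bx, extra)
    x = np.clip(x, bx[:, 0], bx[:, 1])
    boundary = [bool(np.isclose(xi, lo) or np.isclose(xi, hi)) for xi, (lo, hi) in zip(x, bx)]
    natural = {f.name: f.decode(xi) for f, xi in zip(ref.factors, x)}
    return OptimizationResult(
        coded_point=x,
        natural_point=natural,
        value=float(overall(x)),
        boundary=boundary,
        stationary=None,
        n_starts=n_starts + len(extra),
        converged=ok,
        response_values={n: float(m.predict(x)) for n, m in models.items()},
    )


def grid_export(model: QuadraticModel, n: int = 11, box=None) -> pd.DataFrame:
    """Lattice of (coded point, prediction) rows for external plotting.

    ``n`` points per axis over the box; for k = 4 and n = 11 this is
    14,641 rows.  Substitutes for rendered 3-D surface plots.
    """
    bx = _normalize_box(box, model.k)
    axes = [np.linspace(lo, hi, n) for lo, hi in bx]
    pts = np.array(list(itertools.product(*axes)))
    df = pd.DataFrame(pts, columns=[f.name for f in model.factors])
    df["predicted"] = model.predict(pts)
    return df
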