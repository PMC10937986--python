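"""Optimal sample-size selection.

The consistency index ``psi(s)`` falls, on average, as the sample size
``s`` grows.  After min-max standardization of both axes, a cubic
smoothing spline ``h`` fitted to the (size, psi) pairs describes the
trade-off, and the optimal size is the grid point where one extra unit
of (standardized) size buys exactly one unit of (standardized)
consistency:

    s* = argmin_{s in S} | h'(delta(s)) + 1 |

The iterative search grows a prefix of the size grid, always anchored
by the full subset size ``n`` (where psi is exactly 0), refits the
curve, and stops once the same optimum is selected for ``gamma``
consecutive iterations.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, make_smoothing_spline

from .exceptions import CurveFitError, GridError
from .pixel_data import PixelDataset
from .validation import (
    ClassifierSpec,
    ReplicateStats,
    consistency_index,
    replicate_validation,
)

__all__ = [
    "SizeGrid",
    "CurveFit",
    "SizeSearchTrace",
    "build_size_grid",
    "standardize",
    "fit_consistency_curve",
    "select_optimal_size",
    "iterative_size_search",
    "DEFAULT_L",
    "DEFAULT_GAMMA",
]

DEFAULT_L = 10
DEFAULT_GAMMA = 3

# degenerate-psi guard: a psi range below this is treated as flat
_FLAT_TOL = 1e-12


@dataclass(frozen=True)
class SizeGrid:
    """Strictly increasing candidate sizes, ending at the subset size n."""

    sizes: tuple

    def __post_init__(self) -> None:
        s = tuple(int(v) for v in self.sizes)
        if len(s) == 0:
            raise GridError("empty size grid")
        if any(b <= a for a, b in zip(s, s[1:])):
            raise GridError("sizes must be strictly increasing")
        if s[0] < 1:
            raise GridError("sizes must be positive")
        object.__setattr__(self, "sizes", s)

    @property
    def n(self) -> int:
        return self.sizes[-1]

    def __len__(self) -> int:
        return len(self.sizes)

    def __iter__(self):
        return iter(self.sizes)


def build_size_grid(n: int, explicit: list[int] | None = None) -> SizeGrid:
    """The candidate size set S, ending at the subset cardinality ``n``.

    The default grid unions five arithmetic/geometric families —
    hundreds, thousands, tens of thousands, 1e5..3e5 by 4e4, and the
    7*10^i / 15*10^i fill-ins — then drops entries above ``n`` and
    appends ``n`` itself.  For n = 318187 this yields 28 sizes from
    100 to n.
    """
    if explicit is not None:
        sizes = sorted(set(int(v) for v in explicit))
        if any(v > n for v in sizes):
            raise GridError(f"explicit grid entries exceed the subset size {n}")
        if not sizes:
            raise GridError("explicit grid is empty")
        if sizes[-1] != n:
            sizes.append(n)
        return SizeGrid(tuple(sizes))
    default = (
        {100 * i for i in range(1, 6)}
        | {1000 * i for i in range(1, 6)}
        | {10_000 * i for i in range(1, 6)}
        | {40_000 * i + 60_000 for i in range(1, 7)}
        | {7 * 10**i for i in range(2, 5)}
        | {15 * 10**i for i in range(1, 4)}
    )
    sizes = sorted(v for v in default if v <= n)
    if not sizes:
        raise GridError(f"subset size {n} below the smallest default grid entry")
    if sizes[-1] != n:
        sizes.append(n)
    return SizeGrid(tuple(sizes))


def standardize(values) -> np.ndarray:
    """Min-max scaling to [0, 1]."""
    v = np.asarray(values, dtype=float)
    if v.size < 2:
        raise CurveFitError("standardization needs at least 2 values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        raise CurveFitError("cannot standardize a constant vector")
    return (v - lo) / (hi - lo)


@dataclass(frozen=True)
class CurveFit:
    """Cubic smoothing spline through standardized (size, psi) pairs."""

    knots: np.ndarray
    values: np.ndarray
    spline: object

    def derivative(self, x) -> np.ndarray:
        return np.asarray(self.spline.derivative()(np.asarray(x, dtype=float)))

    def __call__(self, x) -> np.ndarray:
        return np.asarray(self.spline(np.asarray(x, dtype=float)))


def fit_consistency_curve(sizes_std, psi_std) -> CurveFit:
    """Fit ``h``: cubic smoothing spline, smoothing chosen by GCV.

    Exactly four points fall back to a natural cubic interpolant
    (GCV smoothing needs at least five).
    """
    x = np.asarray(sizes_std, dtype=float)
    y = np.asarray(psi_std, dtype=float)
    if x.ndim != 1 or x.shape != y.shape:
        raise CurveFitError("sizes and psi values must be equal-length vectors")
    if len(x) < 4:
        raise CurveFitError(f"cubic curve fit needs >= 4 points, got {len(x)}")
    if np.any(np.diff(x) <= 0):
        raise CurveFitError("standardized sizes must be strictly increasing")
    if len(x) == 4:
        spline = CubicSpline(x, y, bc_type="natural")
    else:
        spline = make_smoothing_spline(x, y, lam=None)
    return CurveFit(x, y, spline)


def select_optimal_size(fit: CurveFit, candidates, sizes_std=None) -> int:
    """Candidate minimizing ``|h'(delta(s)) + 1|``; ties go to the smallest s."""
    cand = np.asarray(list(candidates), dtype=int)
    order = np.argsort(cand)
    cand = cand[order]
    x = standardize(cand) if sizes_std is None else np.asarray(sizes_std)[order]
    objective = np.abs(fit.derivative(x) + 1.0)
    best = objective.min()
    # exact/near ties resolved toward the cheapest sample
    winner = int(np.flatnonzero(objective <= best + 1e-9)[0])
    return int(cand[winner])


@dataclass
class SearchIteration:
    index: int
    candidates: tuple
    psi: tuple
    s_star: int
    alpha: int
    degenerate_flat: bool = False


@dataclass
class SizeSearchTrace:
    """Full record of the iterative optimal-size search on one subset."""

    subset_id: int
    l: int
    gamma: int
    iterations: list = field(default_factory=list)
    stats: dict = field(default_factory=dict)  # size -> ReplicateStats
    s_star: int | None = None
    converged: bool = False

    @property
    def alpha(self) -> int:
        return self.iterations[-1].alpha if self.iterations else 0

    @property
    def search_pixels(self) -> int:
        """Distinct sizes evaluated, summed — the sampling cost of the search."""
        return int(sum(self.stats))

    def psi_table(self) -> pd.DataFrame:
        rows = [
            {
                "size": s,
                "phi_bar": st.phi_bar,
                "sigma": st.sigma,
                "psi": self._psi(s),
            }
            for s, st in sorted(self.stats.items())
        ]
        return pd.DataFrame(rows)

    def _psi(self, s: int) -> float:
        ref = self.stats[max(self.stats)]
        return consistency_index(self.stats[s], ref).psi

    def to_json(self, path: str | Path) -> None:
        payload = {
            "subset_id": self.subset_id,
            "l": self.l,
            "gamma": self.gamma,
            "s_star": self.s_star,
            "converged": self.converged,
            "iterations": [
                {
                    "i": it.index,
                    "candidates": list(it.candidates),
                    "psi": list(it.psi),
                    "s_star": it.s_star,
                    "alpha": it.alpha,
                    "degenerate_flat": it.degenerate_flat,
                }
                for it in self.iterations
            ],
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def iterative_size_search(
    data: PixelDataset,
    subset: np.ndarray,
    grid: SizeGrid,
    l: int = DEFAULT_L,
    gamma: int = DEFAULT_GAMMA,
    B: int = 100,
    pi: float = 4.0,
    spec: ClassifierSpec | None = None,
    rng: np.random.Generator | None = None,
    subset_id: int = 0,
    mode: str = "standard",
) -> SizeSearchTrace:
    """Grow-the-grid search for the optimal sample size on one subset.

    Iteration ``i`` fits the consistency curve on the first ``l + i``
    grid sizes plus the full subset size ``n`` and selects a candidate
    optimum; the search stops when the selection repeats for ``gamma``
    consecutive iterations.  Replicate statistics are computed once per
    size and cached, so the validation cost is bounded by the grid
    length regardless of iteration count.
    """
    if l < 3:
        raise GridError("l must be >= 3 (the spline needs at least 4 points)")
    if gamma < 1:
        raise GridError("gamma must be >= 1")
    if spec is None:
        spec = ClassifierSpec()
    if rng is None:
        rng = np.random.default_rng()
    sizes = list(grid)
    n = grid.n
    if len(subset) < n:
        raise GridError(f"subset has {len(subset)} records < grid maximum {n}")
    if len(sizes) < l + 1:
        raise GridError(f"grid with {len(sizes)} sizes too short for l={l}")

    trace = SizeSearchTrace(subset_id=subset_id, l=l, gamma=gamma)

    def stats_for(s: int) -> ReplicateStats:
        if s not in trace.stats:
            trace.stats[s] = replicate_validation(
                data, subset, s, B, pi, spec, rng, subset_id=subset_id, mode=mode
            )
        return trace.stats[s]

    ref = stats_for(n)  # computed exactly once; psi anchor at 0
    alpha = 0
    prev_star: int | None = None
    i = 0
    while l + i < len(sizes) or i == 0:
        i += 1
        xi = sorted(set(sizes[: min(l + i, len(sizes))]) | {n})
        psi = np.array(
            [consistency_index(stats_for(s), ref).psi for s in xi]
        )
        flat = bool(psi.max() - psi.min() < _FLAT_TOL)
        if flat:
            # every size equally consistent (e.g. a perfectly separable
            # image where phi is identically 1): cheapest size wins
            s_star = xi[0]
        else:
            x_std = standardize(xi)
            fit = fit_consistency_curve(x_std, standardize(psi))
            s_star = select_optimal_size(fit, xi, sizes_std=x_std)
        alpha = alpha + 1 if s_star == prev_star else 1
        prev_star = s_star
        trace.iterations.append(
            SearchIteration(i, tuple(xi), tuple(psi), s_star, alpha, flat)
        )
        if alpha >= gamma:
            trace.converged = True
            break
        if l + i >= len(sizes):
            break

    trace.s_star = prev_star
    if not trace.converged:
        warnings.warn(
            f"size search exhausted the grid without {gamma} consecutive "
            f"agreements; returning last selection s*={prev_star}",
            stacklevel=2,
        )
    return trace
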