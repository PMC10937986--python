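"""Generalization across subsets and ranking of segmentation algorithms.

Once the optimal sample size ``s*`` is fixed on one reference subset,
each of the other ``M - 1`` subsets is validated with a single sample
of that size, and the whole-image sensitivity is the mean over all
``M`` subsets:

    phi_bar_D = mean_m phi_bar(m, s*)

Competing segmentation algorithms are ranked by ``phi_bar_D``
(descending), reported alongside min-max normalized scores, and two
rankings are compared with the extended Kendall rank correlation
``tau_X`` (Emond & Mason), which handles ties and equals Kendall's tau
for tie-free rankings.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .exceptions import ParsegError
from .pixel_data import Partition, PixelDataset
from .size_selection import SizeSearchTrace
from .validation import ClassifierSpec, ReplicateStats, replicate_validation

__all__ = [
    "AlgorithmResult",
    "RankingTable",
    "TimingReport",
    "generalize",
    "rank_algorithms",
    "tau_x",
    "time_saving",
    "sampling_percent",
]


@dataclass(frozen=True)
class AlgorithmResult:
    """Validated sensitivity of one segmentation algorithm on one image."""

    label: str
    s_star: int
    per_subset: tuple        # M values phi_bar(m, s*)
    search_pixels: int       # distinct sizes evaluated during the search
    M: int
    trace: SizeSearchTrace | None = None

    @property
    def phi_bar_D(self) -> float:
        return float(np.mean(self.per_subset))

    @property
    def sampling_size(self) -> int:
        """Total pixels consumed: search phase + (M-1) generalization samples."""
        return self.search_pixels + (self.M - 1) * self.s_star


def generalize(
    data: PixelDataset,
    partition: Partition,
    s_star: int,
    j_ref: int,
    stats_ref: ReplicateStats,
    B: int,
    pi: float,
    spec: ClassifierSpec,
    rng: np.random.Generator,
    label: str = "",
    search_pixels: int = 0,
    trace: SizeSearchTrace | None = None,
    mode: str = "standard",
) -> AlgorithmResult:
    """Extend ``s*`` to the remaining ``M - 1`` subsets and average.

    The reference subset re-uses the replicate statistics already
    computed at ``s*`` during the search instead of redrawing.
    """
    min_size = min(partition.sizes())
    if s_star > min_size:
        raise ParsegError(
            f"s*={s_star} exceeds the smallest subset cardinality {min_size}"
        )
    if stats_ref.size != s_star:
        raise ParsegError(
            f"reference stats computed at size {stats_ref.size}, expected {s_star}"
        )
    per_subset = []
    for m, subset in enumerate(partition.subsets):
        if m == j_ref:
            per_subset.append(stats_ref.phi_bar)
            continue
        st = replicate_validation(
            data, subset, s_star, B, pi, spec, rng, subset_id=m, mode=mode
        )
        per_subset.append(st.phi_bar)
    return AlgorithmResult(
        label=label,
        s_star=s_star,
        per_subset=tuple(per_subset),
        search_pixels=search_pixels,
        M=partition.M,
        trace=trace,
    )


@dataclass(frozen=True)
class RankingTable:
    """Algorithms sorted by validated sensitivity, best first."""

    table: pd.DataFrame  # label, phi_bar_D, normalized, rank, s_star, ...

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    def ranks(self) -> dict:
        """label -> rank (1 = best; ties share the mean rank)."""
        return dict(zip(self.table["label"], self.table["rank"]))

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    def __str__(self) -> str:
        return self.table.to_string(index=False, float_format=lambda v: f"{v:.5f}")


def rank_algorithms(results: list[AlgorithmResult], n_total: int | None = None) -> RankingTable:
    """Rank by ``phi_bar_D`` descending with min-max normalized scores.

    With a single algorithm, or all scores equal, every normalized
    score is 1.0 by convention.
    """
    if not results:
        raise ParsegError("no algorithm results to rank")
    phis = np.array([r.phi_bar_D for r in results], dtype=float)
    lo, hi = phis.min(), phis.max()
    normalized = np.ones_like(phis) if hi == lo else (phis - lo) / (hi - lo)
    ranks = rankdata(-phis, method="average")
    rows = []
    for r, phi, norm, rank in zip(results, phis, normalized, ranks):
        row = {
            "label": r.label,
            "phi_bar_D": phi,
            "normalized": norm,
            "rank": rank,
            "s_star": r.s_star,
            "sampling_size": r.sampling_size,
        }
        if n_total:
            row["sampling_pct"] = sampling_percent(r.sampling_size, n_total)
        rows.append(row)
    table = pd.DataFrame(rows).sort_values(
        ["phi_bar_D", "label"], ascending=[False, True], kind="mergesort"
    )
    return RankingTable(table.reset_index(drop=True))


def sampling_percent(sampling_size: int, n_total: int) -> float:
    """Sampled pixels as a percentage of the whole image."""
    if n_total <= 0:
        raise ParsegError("total pixel count must be positive")
    return sampling_size / n_total * 100.0


def _as_rank_vector(ranking) -> tuple[list, np.ndarray]:
    if isinstance(ranking, RankingTable):
        ranking = ranking.ranks()
    if isinstance(ranking, dict):
        items = sorted(ranking)
        return items, np.array([ranking[k] for k in items], dtype=float)
    arr = np.asarray(ranking, dtype=float)
    return list(range(len(arr))), arr


def tau_x(ranking_a, ranking_b) -> float:
    """Extended Kendall rank correlation (Emond & Mason) between rankings.

    Accepts rank vectors (lower = better), ``{item: rank}`` dicts, or
    :class:`RankingTable` objects; dict/table inputs are matched by
    item.  Score matrices use +1 for "ranked ahead of or tied with",
    -1 for "behind"; tau_X is the normalized inner product and equals
    Kendall's tau when there are no ties.
    """
    items_a, ra = _as_rank_vector(ranking_a)
    items_b, rb = _as_rank_vector(ranking_b)
    if items_a != items_b:
        raise ParsegError(f"rankings cover different items: {items_a} vs {items_b}")
    if len(ra) != len(rb) or len(ra) < 2:
        raise ParsegError("rankings must cover the same >= 2 items")
    if np.isnan(ra).any() or np.isnan(rb).any():
        raise ParsegError("incomplete ranking: missing rank values")

    def scores(r: np.ndarray) -> np.ndarray:
        a = np.where(r[:, None] <= r[None, :], 1.0, -1.0)
        np.fill_diagonal(a, 0.0)
        return a

    n = len(ra)
    return float((scores(ra) * scores(rb)).sum() / (n * (n - 1)))


@dataclass(frozen=True)
class TimingReport:
    """Wall-clock comparison: whole-image vs sample-based validation."""

    T_i: float  # minutes, whole image
    T_s: float  # minutes, sample-based

    @property
    def delta(self) -> float:
        return time_saving(self.T_i, self.T_s)


def time_saving(T_i: float, T_s: float) -> float:
    """Percentage of validation time saved: (T_i - T_s) / T_i * 100."""
    if T_i <= 0:
        raise ParsegError("whole-image time must be positive")
    return (T_i - T_s) / T_i * 100.0
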