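"""Model/Results interface for the validation procedure.

:class:`SegmentationValidation` is built from an image plus one or
more candidate binary masks; ``fit()`` runs the four stages —
partitioning, random selection, estimation, generalization — for every
candidate and returns a :class:`ValidationResults` carrying the
per-algorithm sensitivities, optimal sample sizes, search diagnostics,
the ranking table and wall-clock timing.  ``fit(whole_image=True)``
runs the exhaustive baseline (every subset validated at its full
cardinality) against which the sampled procedure is judged.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from ._rng import substream
from .exceptions import ParsegError
from .pixel_data import (
    BinaryMask,
    Partition,
    PixelDataset,
    RGBImage,
    build_pixel_dataset,
    load_binary_mask,
    load_rgb_image,
    stratified_partition,
)
from .ranking import (
    AlgorithmResult,
    RankingTable,
    TimingReport,
    generalize,
    rank_algorithms,
    tau_x,
)
from .size_selection import (
    DEFAULT_GAMMA,
    DEFAULT_L,
    build_size_grid,
    iterative_size_search,
)
from .validation import ClassifierSpec, ReplicateStats, replicate_validation

__all__ = ["SegmentationValidation", "ValidationResults"]

logger = logging.getLogger("parseg")


@dataclass
class ValidationResults:
    """Fitted results: estimates, diagnostics, ranking and timing."""

    mode: str                      # "sample" | "whole"
    results: dict                  # label -> AlgorithmResult
    ranking: RankingTable
    n_total: int
    M: int
    seed: int
    elapsed_minutes: dict          # label -> minutes
    reference_subsets: dict        # label -> j_ref (sample mode)

    @property
    def phi_bar_D(self) -> dict:
        """label -> whole-image average sensitivity."""
        return {k: v.phi_bar_D for k, v in self.results.items()}

    def summary(self) -> str:
        lines = [
            "Segmentation validation" + (" (whole-image baseline)" if self.mode == "whole" else ""),
            f"  pixels N={self.n_total}, subsets M={self.M}, seed={self.seed}",
            "",
            str(self.ranking),
        ]
        return "\n".join(lines)

    def timing_against(self, whole: "ValidationResults") -> TimingReport:
        """Time saved versus a whole-image run of the same inputs."""
        return TimingReport(
            T_i=sum(whole.elapsed_minutes.values()),
            T_s=sum(self.elapsed_minutes.values()),
        )

    def tau_x_against(self, other: "ValidationResults") -> float:
        """Rank agreement with another run over the same algorithms."""
        return tau_x(self.ranking, other.ranking)

    def plot_search(self, label: str, ax=None):
        """Standardized size-vs-psi curve with the fitted spline and the
        tangent point where the derivative equals -1 (sample mode only)."""
        res = self.results.get(label)
        if res is None or res.trace is None:
            raise ParsegError(f"no search trace for {label!r}")
        import matplotlib.pyplot as plt

        from .size_selection import fit_consistency_curve, standardize

        if ax is None:
            _, ax = plt.subplots()
        last = res.trace.iterations[-1]
        xi = np.array(last.candidates)
        psi = np.array(last.psi)
        if psi.max() - psi.min() <= 0:
            ax.plot(standardize(xi), psi, "o")
            ax.set_title(f"{label}: flat consistency curve")
            return ax
        x, y = standardize(xi), standardize(psi)
        fit = fit_consistency_curve(x, y)
        grid = np.linspace(0, 1, 200)
        ax.plot(x, y, "o", label=r"$(\delta(s), \delta(\psi))$")
        ax.plot(grid, fit(grid), "--", label="cubic spline $h$")
        star = standardize(xi)[list(xi).index(res.s_star)]
        ax.plot(star, float(fit(star)), "ro", label=f"$s^*={res.s_star}$")
        ax.set_xlabel(r"standardized size $\delta(s)$")
        ax.set_ylabel(r"standardized consistency $\delta(\psi)$")
        ax.legend()
        ax.set_title(label)
        return ax

    def to_report(self) -> dict:
        """JSON-serializable run report."""
        return {
            "mode": self.mode,
            "N": self.n_total,
            "M": self.M,
            "seed": self.seed,
            "algorithms": {
                label: {
                    "phi_bar_D": res.phi_bar_D,
                    "s_star": res.s_star,
                    "sampling_size": res.sampling_size,
                    "per_subset": list(res.per_subset),
                    "minutes": self.elapsed_minutes[label],
                }
                for label, res in self.results.items()
            },
            "ranking": self.ranking.table.to_dict(orient="records"),
        }


@dataclass
class SegmentationValidation:
    """Validate candidate binary segmentations of one RGB image.

    Parameters mirror the procedure's study defaults: ``M=40``
    subsets, ``B=100`` classifier replicates, learning/validation
    ratio ``pi=4``, CART classifier; the search parameters ``l=10``
    and ``gamma=3`` govern the first spline fit and the stability
    requirement of the optimal-size search.
    """

    image: RGBImage
    masks: dict                      # label -> BinaryMask
    M: int = 40
    B: int = 100
    pi: float = 4.0
    l: int = DEFAULT_L
    gamma: int = DEFAULT_GAMMA
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    size_grid: list | None = None    # explicit grid; default built per subset
    seed: int = 0
    sensitivity_mode: str = "standard"

    def __post_init__(self) -> None:
        if not self.masks:
            raise ParsegError("no candidate masks")
        for label, mask in self.masks.items():
            if (mask.height, mask.width) != (self.image.height, self.image.width):
                raise ParsegError(
                    f"mask {label!r} is {mask.height}x{mask.width}, "
                    f"image is {self.image.height}x{self.image.width}"
                )

    @classmethod
    def from_files(cls, image_path: str | Path, manifest_path: str | Path, **kwargs):
        """Build from an image file and a manifest CSV of candidate masks.

        The manifest has columns ``algorithm_label, mask_path`` with
        paths relative to the manifest's directory.
        """
        image = load_rgb_image(image_path)
        manifest = pd.read_csv(manifest_path)
        if manifest.empty:
            raise ParsegError(f"no candidate masks listed in {manifest_path}")
        base = Path(manifest_path).parent
        masks = {
            str(row["algorithm_label"]): load_binary_mask(base / str(row["mask_path"]))
            for _, row in manifest.iterrows()
        }
        return cls(image=image, masks=masks, **kwargs)

    # ------------------------------------------------------------------

    def _dataset(self, label: str) -> PixelDataset:
        return build_pixel_dataset(self.image, self.masks[label])

    def _partition(self, label: str, data: PixelDataset) -> Partition:
        return stratified_partition(
            data, self.M, substream(self.seed, "partition", label)
        )

    def fit(self, whole_image: bool = False) -> ValidationResults:
        """Run the procedure for every candidate mask and rank them."""
        results: dict[str, AlgorithmResult] = {}
        minutes: dict[str, float] = {}
        refs: dict[str, int] = {}
        for label in self.masks:
            t0 = time.perf_counter()
            stage = "build dataset"
            try:
                data = self._dataset(label)
                stage = "partition"
                partition = self._partition(label, data)
                if whole_image:
                    stage = "whole-image validation"
                    results[label] = self._fit_whole(label, data, partition)
                else:
                    stage = "size search / generalization"
                    results[label], refs[label] = self._fit_sampled(
                        label, data, partition
                    )
            except ParsegError as exc:
                raise ParsegError(f"[{label} / {stage}] {exc}") from exc
            minutes[label] = (time.perf_counter() - t0) / 60.0
            logger.info(
                "algorithm=%s stage=done phi_bar_D=%.5f minutes=%.2f",
                label, results[label].phi_bar_D, minutes[label],
            )
        n_total = self.image.n_pixels
        ranking = rank_algorithms(list(results.values()), n_total=n_total)
        return ValidationResults(
            mode="whole" if whole_image else "sample",
            results=results,
            ranking=ranking,
            n_total=n_total,
            M=self.M,
            seed=self.seed,
            elapsed_minutes=minutes,
            reference_subsets=refs,
        )

    def _fit_sampled(self, label, data, partition):
        rng = substream(self.seed, "validate", label)
        j_ref = int(rng.integers(partition.M))
        subset = partition.subsets[j_ref]
        grid = build_size_grid(len(subset), explicit=self.size_grid)
        logger.info(
            "algorithm=%s stage=search subset=%d n=%d grid=%d sizes",
            label, j_ref, len(subset), len(grid),
        )
        trace = iterative_size_search(
            data,
            subset,
            grid,
            l=self.l,
            gamma=self.gamma,
            B=self.B,
            pi=self.pi,
            spec=self.classifier,
            rng=rng,
            subset_id=j_ref,
            mode=self.sensitivity_mode,
        )
        s_star = min(trace.s_star, min(partition.sizes()))
        stats_ref = trace.stats[trace.s_star]
        logger.info("algorithm=%s stage=generalize s_star=%d", label, s_star)
        result = generalize(
            data,
            partition,
            s_star,
            j_ref,
            stats_ref if stats_ref.size == s_star else replicate_validation(
                data, subset, s_star, self.B, self.pi, self.classifier, rng,
                subset_id=j_ref, mode=self.sensitivity_mode,
            ),
            self.B,
            self.pi,
            self.classifier,
            rng,
            label=label,
            search_pixels=trace.search_pixels,
            trace=trace,
            mode=self.sensitivity_mode,
        )
        return result, j_ref

    def _fit_whole(self, label, data, partition) -> AlgorithmResult:
        rng = substream(self.seed, "whole", label)
        per_subset = []
        for m, subset in enumerate(partition.subsets):
            st: ReplicateStats = replicate_validation(
                data,
                subset,
                len(subset),
                self.B,
                self.pi,
                self.classifier,
                rng,
                subset_id=m,
                mode=self.sensitivity_mode,
            )
            per_subset.append(st.phi_bar)
        return AlgorithmResult(
            label=label,
            s_star=partition.n,
            per_subset=tuple(per_subset),
            search_pixels=0,
            M=partition.M,
        )
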