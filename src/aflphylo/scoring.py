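"""Peak-height scoring: threshold optimisation driven by replicate error rates.

The workflow: retain loci whose mean height
(over non-replicate profiles) clears a retention threshold, call presence
by an absolute or relative (fraction-of-locus-mean) threshold, estimate
mismatch error from replicate pairs, and pick the grid point minimising
error subject to a locus-retention floor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data import BinaryCharacterMatrix, PeakHeightTable
from .errors import AflPhyloError, EmptyMatrixError, InfeasibleGridError

__all__ = [
    "ScoringThresholds",
    "ErrorRateReport",
    "GridSpec",
    "call_phenotypes",
    "estimate_mismatch_error_rate",
    "optimize_thresholds",
    "filter_unique_loci",
    "FilterResult",
    "drop_replicate_rows",
]


@dataclass(frozen=True)
class ScoringThresholds:
    retention_threshold: float
    calling_mode: str  # "absolute" | "relative"
    calling_threshold: float

    def __post_init__(self) -> None:
        if self.retention_threshold < 0:
            raise AflPhyloError("retention_threshold must be >= 0")
        if self.calling_mode == "relative":
            if not 0.0 < self.calling_threshold <= 1.0:
                raise AflPhyloError("relative calling_threshold must be in (0, 1]")
        elif self.calling_mode == "absolute":
            if self.calling_threshold <= 0:
                raise AflPhyloError("absolute calling_threshold must be > 0")
        else:
            raise AflPhyloError("calling_mode must be 'absolute' or 'relative'")


@dataclass
class ErrorRateReport:
    per_locus_error: dict[str, float]
    overall_error: float        # unweighted mean of per-locus errors
    pair_mean_error: float      # mean over replicate pairs of per-pair error
    n_retained_loci: int
    n_pairs: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.overall_error <= 1.0:
            raise AflPhyloError("overall_error out of [0, 1]")


def _locus_means(peaks: PeakHeightTable) -> np.ndarray:
    primary = peaks.primary_rows()
    if not primary.any():
        raise AflPhyloError("no non-replicate rows in peak table")
    return peaks.heights[primary].mean(axis=0)


def call_phenotypes(
    peaks: PeakHeightTable, thresholds: ScoringThresholds
) -> BinaryCharacterMatrix:
    """Binary calls for all rows (replicates included) over retained loci.

    Loci whose mean height over non-replicate rows falls below the
    retention threshold are dropped. The species map covers non-replicate
    rows only; use :func:`drop_replicate_rows` before tree building.
    """
    means = _locus_means(peaks)
    retained = np.flatnonzero(means >= thresholds.retention_threshold)
    if retained.size == 0:
        raise EmptyMatrixError(
            f"retention_threshold={thresholds.retention_threshold} drops every locus"
        )
    h = peaks.heights[:, retained]
    if thresholds.calling_mode == "absolute":
        calls = h >= thresholds.calling_threshold
    else:
        calls = h >= thresholds.calling_threshold * means[retained][None, :]
    locus_ids = [f"bin{peaks.bin_sizes[j]:g}" for j in retained]
    species_map = {s: sp for s, sp in peaks.species_map.items()
                   if s not in peaks.replicate_row_ids}
    return BinaryCharacterMatrix(calls.astype(np.int8), list(peaks.sample_ids),
                                 locus_ids, species_map)


def estimate_mismatch_error_rate(
    calls: BinaryCharacterMatrix, replicate_pairs: list[tuple[str, str]]
) -> ErrorRateReport:
    """Replicate discordance per locus and averaged.

    Per-locus error is the fraction of replicate pairs disagreeing at that
    locus. ``overall_error`` averages over loci; ``pair_mean_error``
    averages per-pair mismatch fractions — with a full pair x locus grid
    the two coincide, both are reported for transparency.
    """
    if not replicate_pairs:
        raise AflPhyloError("at least one replicate pair is required")
    pos = {s: i for i, s in enumerate(calls.sample_ids)}
    for a, b in replicate_pairs:
        if a not in pos or b not in pos:
            raise AflPhyloError(f"replicate pair ({a}, {b}) not present in calls")
    a_idx = [pos[a] for a, _ in replicate_pairs]
    b_idx = [pos[b] for _, b in replicate_pairs]
    diff = (calls.calls[a_idx] != calls.calls[b_idx])
    per_locus = diff.mean(axis=0)
    per_pair = diff.mean(axis=1)
    return ErrorRateReport(
        per_locus_error=dict(zip(calls.locus_ids, per_locus.astype(float))),
        overall_error=float(per_locus.mean()),
        pair_mean_error=float(per_pair.mean()),
        n_retained_loci=calls.n_loci,
        n_pairs=len(replicate_pairs),
    )


@dataclass
class GridSpec:
    """Search grid for threshold optimisation.

    Defaults: retention 0-500 in 26 steps; relative calling 5%-50% in 10
    steps; absolute calling spread over the observed height range.
    """

    retention_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.0, 500.0, 26)
    )
    relative_grid: np.ndarray = field(
        default_factory=lambda: np.linspace(0.05, 0.50, 10)
    )
    absolute_grid: np.ndarray | None = None  # default derived from data
    modes: tuple[str, ...] = ("absolute", "relative")
    min_retained_frac: float = 0.2

    def absolute_for(self, peaks: PeakHeightTable) -> np.ndarray:
        if self.absolute_grid is not None:
            return np.asarray(self.absolute_grid, dtype=float)
        hi = float(peaks.heights.max())
        if hi <= 0:
            hi = 1.0
        return np.linspace(0.05 * hi, 0.75 * hi, 10)


def optimize_thresholds(
    peaks: PeakHeightTable, grid_spec: GridSpec | None = None
) -> tuple[ScoringThresholds, ErrorRateReport]:
    """Grid search minimising overall mismatch error.

    Feasible points retain at least ``min_retained_frac`` of loci. Ties
    break towards more *polymorphic* retained loci (degenerate thresholds
    that call everything present score zero error but zero information),
    then more retained loci, then lower retention threshold, then lower
    calling threshold. Both calling modes are evaluated and the better
    kept.
    """
    if not peaks.replicate_pairs:
        raise AflPhyloError("threshold optimisation needs at least one replicate pair")
    grid = grid_spec or GridSpec()
    n_total = peaks.n_bins
    best: tuple | None = None
    best_result: tuple[ScoringThresholds, ErrorRateReport] | None = None
    for mode in grid.modes:
        calling_values = (grid.relative_grid if mode == "relative"
                          else grid.absolute_for(peaks))
        for rt in np.asarray(grid.retention_grid, dtype=float):
            for ct in np.asarray(calling_values, dtype=float):
                thresholds = ScoringThresholds(float(rt), mode, float(ct))
                try:
                    calls = call_phenotypes(peaks, thresholds)
                except EmptyMatrixError:
                    continue
                if calls.n_loci < grid.min_retained_frac * n_total:
                    continue
                report = estimate_mismatch_error_rate(calls, peaks.replicate_pairs)
                n_poly = int(calls.polymorphic_mask().sum())
                key = (report.overall_error, -n_poly, -report.n_retained_loci, rt, ct)
                if best is None or key < best:
                    best = key
                    best_result = (thresholds, report)
    if best_result is None:
        raise InfeasibleGridError(
            f"no grid point retains >= {grid.min_retained_frac:.0%} of {n_total} loci"
        )
    return best_result


@dataclass
class FilterResult:
    matrix: BinaryCharacterMatrix
    collapse_map: dict[str, list[str]]  # representative locus -> collapsed duplicates
    n_monomorphic_dropped: int


def filter_unique_loci(
    matrix: BinaryCharacterMatrix,
    drop_monomorphic: bool = True,
    collapse_duplicates: bool = True,
) -> FilterResult:
    """Reduce to 'unique loci': polymorphic, duplicate columns collapsed.

    Identical call columns are presumed size-homoplasy artifacts; the first
    column of each identity class survives and the collapse map records the
    rest. Idempotent.
    """
    keep = np.ones(matrix.n_loci, dtype=bool)
    n_mono = 0
    if drop_monomorphic:
        poly = matrix.polymorphic_mask()
        n_mono = int((~poly).sum())
        keep &= poly
    collapse_map: dict[str, list[str]] = {}
    if collapse_duplicates:
        seen: dict[bytes, int] = {}
        for j in np.flatnonzero(keep):
            key = matrix.calls[:, j].tobytes()
            if key in seen:
                rep = seen[key]
                collapse_map.setdefault(matrix.locus_ids[rep], []).append(matrix.locus_ids[j])
                keep[j] = False
            else:
                seen[key] = j
    if not keep.any():
        raise EmptyMatrixError("filtering removed every locus")
    return FilterResult(matrix.subset_loci(np.flatnonzero(keep)), collapse_map, n_mono)


def drop_replicate_rows(
    calls: BinaryCharacterMatrix, replicate_pairs: list[tuple[str, str]]
) -> BinaryCharacterMatrix:
    """Remove the duplicate profiles once the error rate has been estimated."""
    reps = {b for _, b in replicate_pairs}
    keep = [s for s in calls.sample_ids if s not in reps]
    return calls.subset_samples(keep)
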