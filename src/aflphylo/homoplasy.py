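"""Leave-one-species-out homoplasy excess test for hybrid detection.

A hybrid taxon carries a per-locus mosaic of its parents' characters, which
injects homoplasy into clades containing the parents and depresses their
bootstrap support. Removing the hybrid removes that homoplasy, so support
for the parental clades jumps. The test removes one species at a time,
re-bootstraps, records per-bipartition support deltas against the full-data
baseline, and flags removals producing outlier increases.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np

from .data import BinaryCharacterMatrix
from .errors import AflPhyloError, NoSignalError
from .nj import SupportTable, bootstrap_support
from .trees import Bipartition, restrict_bipartition

__all__ = [
    "OutlierRule",
    "RemovalRecord",
    "HomoplasyExcessResult",
    "leave_one_out_support",
    "detect_hybrids",
    "run_homoplasy_excess",
]


@dataclass(frozen=True)
class OutlierRule:
    """How a support increase qualifies as an outlier.

    ``tukey``: delta must exceed Q3 + 1.5*IQR of the per-bipartition delta
    distribution. ``zscore``: delta must exceed mean + z*sd. ``floor``: no
    distribution-based fence — only the fixed ``min_delta`` threshold,
    calibrated against bootstrap support noise (at 100 pseudoreplicates the
    support standard error is at most ~5 points, so a floor of 8-10 points
    sits 2-3 SEs above the null). Every mode additionally requires the
    increase to reach ``min_delta`` percentage points, which guards against
    fences collapsing when the distribution is tight.
    """

    fence: str = "tukey"
    min_delta: float = 10.0
    iqr_factor: float = 1.5
    z: float = 3.0

    def __post_init__(self) -> None:
        if self.fence not in ("tukey", "zscore", "floor"):
            raise AflPhyloError("fence must be 'tukey', 'zscore' or 'floor'")
        if self.min_delta < 0:
            raise AflPhyloError("min_delta must be >= 0")

    def fence_value(self, deltas: np.ndarray) -> float:
        deltas = np.asarray(deltas, dtype=float)
        if self.fence == "tukey":
            q1, q3 = np.percentile(deltas, [25, 75])
            return float(q3 + self.iqr_factor * (q3 - q1))
        if self.fence == "zscore":
            return float(deltas.mean() + self.z * deltas.std(ddof=0))
        return float("-inf")


@dataclass
class RemovalRecord:
    removed_species: str
    support_after: SupportTable
    # BASELINE bipartition -> (support_after(restriction) - baseline), points.
    # Keying by the full-tree split keeps node identity comparable across
    # removals, whose restricted forms live on different leaf sets.
    deltas: dict[Bipartition, float]
    # baseline bipartition -> its restriction onto the reduced leaf set
    restricted: dict[Bipartition, Bipartition] = field(default_factory=dict)
    novel_bipartitions: set[Bipartition] = field(default_factory=set)


@dataclass
class HomoplasyExcessResult:
    baseline: SupportTable
    records: list[RemovalRecord]
    outliers: list[tuple[str, Bipartition, float, float]]  # species, bip, delta, fence
    verdict_per_species: dict[str, str]  # "flagged" | "not_flagged"
    parameters: OutlierRule = field(default_factory=OutlierRule)

    def flagged_species(self) -> list[str]:
        return [sp for sp, v in self.verdict_per_species.items() if v == "flagged"]

    def candidate_parent_clades(self, species: str) -> list[Bipartition]:
        return [bp for sp, bp, _, _ in self.outliers if sp == species]


def _derived_seed(master_seed: int, label: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{label}".encode()).digest()
    return int.from_bytes(digest[:8], "big") % (2**63)


def _species_split(bp: Bipartition, species_map: dict[str, str],
                   species_universe: frozenset) -> Bipartition | None:
    """Project a sample-level split to species level, or ``None``.

    Returns a split over species labels when the sample split is
    species-coherent (no species straddles the split) and non-trivial at
    species level. Within-species splits and single-species clades carry
    no information about relationships *among* species, which is what the
    homoplasy excess test interrogates.
    """
    side_species = {species_map[s] for s in bp.side}
    comp_species = {species_map[s] for s in bp.complement}
    if side_species & comp_species:
        return None  # not species-coherent
    out = Bipartition.of(side_species, species_universe)
    if out.is_trivial():
        return None
    return out


def _expand_to_samples(species_side: frozenset, matrix: BinaryCharacterMatrix) -> Bipartition:
    samples = [s for s in matrix.sample_ids if matrix.species_map.get(s) in species_side]
    return Bipartition.of(samples, matrix.sample_ids)


def leave_one_out_support(
    matrix: BinaryCharacterMatrix,
    n_boot: int,
    seed: int,
    baseline: SupportTable | None = None,
    transform: str = "one-minus-f",
) -> tuple[SupportTable, list[RemovalRecord]]:
    """Drop each species in turn and re-bootstrap against the full-data baseline.

    Removals are independent: the baseline is always the full dataset.
    Support bookkeeping happens on species-level bipartitions (nodes that
    split individuals within a species, or cut off a single species, carry
    no information about relationships *among* species). The tracked node
    set is the union of the baseline point tree's species splits and every
    reduced point tree's species splits embedded back into the full
    universe — a hybrid that *stably* displaces true structure leaves the
    restored node visible only in its own reduced tree, so baseline-only
    bookkeeping would be blind to exactly the strongest signals. Supports
    for all queries are counted from stored per-replicate split sets.
    Per-removal seeds derive from the master seed and the species label,
    independent of iteration order.

    Returns ``(species-level baseline SupportTable, records)``; deltas are
    keyed by the full-universe species split.
    """
    from .trees import tree_bipartitions

    species = matrix.species()
    if len(species) < 4:
        raise AflPhyloError("leave-one-out needs at least 4 species")
    missing = [s for s in matrix.sample_ids if s not in matrix.species_map]
    if missing:
        raise AflPhyloError(f"samples without species assignment: {missing[:5]}")
    sp_universe = frozenset(species)
    if baseline is None or baseline.replicate_splits is None:
        base_tree, baseline = bootstrap_support(matrix, n_boot, seed,
                                                transform=transform,
                                                collect_splits=True)
    else:
        base_tree = None

    # reduced bootstraps, replicate splits kept for post-hoc queries
    reduced_runs: dict[str, tuple] = {}
    for sp in species:
        if len(matrix.rows_for_species(sp)) == matrix.n_samples:
            raise AflPhyloError(f"species {sp!r} comprises the whole dataset")
        reduced = matrix.drop_species(sp)
        red_tree, red_support = bootstrap_support(
            reduced, n_boot, _derived_seed(seed, sp),
            transform=transform, collect_splits=True,
        )
        reduced_runs[sp] = (reduced, red_tree, red_support)

    # query set: species-level splits of the baseline point tree. Splits
    # appearing only in reduced trees are NOT promoted to queries: every
    # species' removal trivially "reveals" the clade it was nested inside,
    # so novel-split deltas would flag every taxon, hybrid or not. They are
    # reported informationally on each record instead.
    queries: set[Bipartition] = set()

    def _project(tree, species_map, universe):
        out = set()
        for bp in tree_bipartitions(tree):
            sbp = _species_split(bp, species_map, universe)
            if sbp is not None:
                out.add(sbp)
        return out

    if base_tree is not None:
        queries |= _project(base_tree, matrix.species_map, sp_universe)
    else:  # caller-supplied baseline: project its counted (point-tree) splits
        for bp in baseline.entries:
            sbp = _species_split(bp, matrix.species_map, sp_universe)
            if sbp is not None:
                queries.add(sbp)

    def _support(table: SupportTable, side_species, mat: BinaryCharacterMatrix):
        return table.support_of(_expand_to_samples(side_species, mat))

    baseline_entries = {q: _support(baseline, q.side, matrix) for q in queries}
    baseline_sp = SupportTable(baseline_entries, baseline.n_pseudoreplicates,
                               baseline.n_redrawn)

    records: list[RemovalRecord] = []
    for sp in species:
        reduced, red_tree, red_support = reduced_runs[sp]
        deltas: dict[Bipartition, float] = {}
        restricted: dict[Bipartition, Bipartition] = {}
        after_entries: dict[Bipartition, float] = {}
        for q in queries:
            rbp = restrict_bipartition(q, {sp})
            if rbp is None:
                continue
            expanded = _expand_to_samples(rbp.side, reduced)
            after = red_support.support_of(expanded)
            deltas[q] = after - baseline_entries[q]
            restricted[q] = rbp
            after_entries[expanded] = after
        novel = tree_bipartitions(red_tree) - set(after_entries)
        records.append(RemovalRecord(
            sp,
            SupportTable(after_entries, red_support.n_pseudoreplicates,
                         red_support.n_redrawn),
            deltas,
            restricted,
            novel,
        ))
    return baseline_sp, records


def detect_hybrids(
    baseline: SupportTable,
    records: list[RemovalRecord],
    rule: OutlierRule | None = None,
) -> HomoplasyExcessResult:
    """Apply the outlier rule to the per-bipartition delta distributions.

    For every bipartition that survives restriction under at least three
    removals, the deltas across removals form the distribution; removals
    whose delta exceeds the fence *and* the minimum-increase floor are
    outliers, and those species are flagged as putative hybrids. The
    strengthened bipartitions are the candidate parental clades.
    """
    rule = rule or OutlierRule()
    if len(records) < 3:
        raise AflPhyloError("need at least 3 removal records to form distributions")
    by_bip: dict[Bipartition, list[tuple[str, float]]] = {}
    for rec in records:
        for bp, delta in rec.deltas.items():
            by_bip.setdefault(bp, []).append((rec.removed_species, delta))
    usable = {bp: pairs for bp, pairs in by_bip.items() if len(pairs) >= 3}
    if not usable:
        raise NoSignalError("no bipartition retains a delta distribution across removals")
    outliers: list[tuple[str, Bipartition, float, float]] = []
    flagged: set[str] = set()
    for bp, pairs in usable.items():
        deltas = np.array([d for _, d in pairs])
        fence = rule.fence_value(deltas)
        for sp, d in pairs:
            if d > fence and d >= rule.min_delta:
                outliers.append((sp, bp, float(d), float(fence)))
                flagged.add(sp)
    verdict = {rec.removed_species: ("flagged" if rec.removed_species in flagged
                                     else "not_flagged")
               for rec in records}
    return HomoplasyExcessResult(baseline, records, outliers, verdict, rule)


def run_homoplasy_excess(
    matrix: BinaryCharacterMatrix,
    n_boot: int,
    seed: int,
    rule: OutlierRule | None = None,
    transform: str = "one-minus-f",
) -> HomoplasyExcessResult:
    """Convenience driver: baseline bootstrap, leave-one-out, outlier detection."""
    baseline, records = leave_one_out_support(matrix, n_boot, seed, transform=transform)
    return detect_hybrids(baseline, records, rule)
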