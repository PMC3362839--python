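"""Neighbour joining and locus-resampling bootstrap support.

The agglomeration core is shared between the tree builder (used for point
estimates) and a lean split collector (used inside the bootstrap loop,
where only bipartition membership matters).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np

from .data import BinaryCharacterMatrix
from .distance import DistanceMatrix, _apply_transform, _pairwise_f
from .errors import AflPhyloError, UndefinedDistanceError
from .trees import Bipartition, build_tree, tree_bipartitions

__all__ = ["SupportTable", "neighbor_joining", "bootstrap_support"]


@dataclass
class SupportTable:
    """Bootstrap support (percent) per canonical bipartition.

    ``replicate_splits`` (kept only when requested) holds each
    pseudoreplicate tree's full split set, enabling post-hoc support
    queries for bipartitions not known at bootstrap time.
    """

    entries: dict[Bipartition, float]
    n_pseudoreplicates: int
    n_redrawn: int = 0
    replicate_splits: list[set] | None = None

    def get(self, bp: Bipartition, default=None):
        return self.entries.get(bp, default)

    def items(self):
        return self.entries.items()

    def support_of(self, bp: Bipartition) -> float:
        """Support for an arbitrary split, via stored replicate split sets."""
        if bp in self.entries:
            return self.entries[bp]
        if self.replicate_splits is None:
            raise AflPhyloError(
                "split not counted during the bootstrap and replicate splits "
                "were not collected"
            )
        hits = sum(bp in s for s in self.replicate_splits)
        return 100.0 * hits / self.n_pseudoreplicates


def _nj_merge_order(d: np.ndarray, rep_labels: list[str]):
    """Run Saitou-Nei agglomeration; return merge events and the final join.

    Returns ``(merges, final)`` where each merge is
    ``(id_i, id_j, new_id, v_i, v_j)`` and ``final`` is a list of
    ``(id, edge_length)`` for the last three clusters joined at the
    unrooted seed node. Q-matrix ties are broken by the lexicographic order
    of each cluster's smallest leaf label.
    """
    n0 = d.shape[0]
    d = d.astype(float).copy()
    active_ids = list(range(n0))
    reps = list(rep_labels)  # representative label (min leaf label) per active cluster
    next_id = n0
    merges = []
    while len(active_ids) > 3:
        n = len(active_ids)
        r = d.sum(axis=1)
        q = (n - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        cand = np.argwhere(q <= qmin)  # exact ties only (identical floats)
        best = None
        best_key = None
        for i, j in cand:
            if i > j:
                i, j = j, i
            key = tuple(sorted((reps[i], reps[j])))
            if best_key is None or key < best_key:
                best_key = key
                best = (i, j)
        i, j = best
        dij = d[i, j]
        v_i = 0.5 * dij + (r[i] - r[j]) / (2.0 * (n - 2))
        v_j = dij - v_i
        # clamp negative estimates, push the deficit onto the sibling edge
        if v_i < 0:
            v_j += v_i
            v_i = 0.0
        if v_j < 0:
            v_i += v_j
            v_j = 0.0
        v_i = max(v_i, 0.0)
        v_j = max(v_j, 0.0)
        new_row = 0.5 * (d[i] + d[j] - dij)
        merges.append((active_ids[i], active_ids[j], next_id, v_i, v_j))
        # replace cluster i with the merged cluster, delete j
        d[i, :] = new_row
        d[:, i] = new_row
        d[i, i] = 0.0
        keep = np.arange(n) != j
        d = d[np.ix_(keep, keep)]
        active_ids[i] = next_id
        reps[i] = min(reps[i], reps[j])
        del active_ids[j]
        del reps[j]
        next_id += 1
    if len(active_ids) == 3:
        va = 0.5 * (d[0, 1] + d[0, 2] - d[1, 2])
        vb = 0.5 * (d[0, 1] + d[1, 2] - d[0, 2])
        vc = 0.5 * (d[0, 2] + d[1, 2] - d[0, 1])
        final = [
            (active_ids[0], max(va, 0.0)),
            (active_ids[1], max(vb, 0.0)),
            (active_ids[2], max(vc, 0.0)),
        ]
    else:  # exactly 3 never reduces below; n0 == 3 arrives here directly
        raise AflPhyloError("neighbour joining requires at least 3 taxa")
    return merges, final


def neighbor_joining(dm: DistanceMatrix) -> dendropy.Tree:
    """Unrooted NJ tree from a validated distance matrix.

    Deterministic: Q ties resolve by lexicographic label-pair order.
    Negative branch-length estimates are clamped to zero with the deficit
    moved to the sibling edge.
    """
    if dm.n < 3:
        raise AflPhyloError("neighbour joining requires at least 3 taxa")
    merges, final = _nj_merge_order(dm.d, dm.labels)
    edges: dict[int, tuple[int | None, float]] = {}
    for id_i, id_j, new_id, v_i, v_j in merges:
        edges[id_i] = (new_id, v_i)
        edges[id_j] = (new_id, v_j)
    root_id = max(nid for nid, _ in final) + 1
    for nid, length in final:
        edges[nid] = (root_id, length)
    edges[root_id] = (None, 0.0)
    return build_tree(edges, dm.labels)


def _nj_splits(d: np.ndarray, labels: list[str]) -> set[Bipartition]:
    """Non-trivial splits of the NJ tree without building a tree object."""
    n = d.shape[0]
    merges, _ = _nj_merge_order(d, labels)
    members: dict[int, frozenset] = {i: frozenset((labels[i],)) for i in range(n)}
    universe = frozenset(labels)
    out: set[Bipartition] = set()
    for id_i, id_j, new_id, _, _ in merges:
        merged = members[id_i] | members[id_j]
        members[new_id] = merged
        if 2 <= len(merged) <= n - 2:
            out.add(Bipartition.of(merged, universe))
    return out


def bootstrap_support(
    matrix: BinaryCharacterMatrix,
    n_pseudoreplicates: int,
    seed: int,
    transform: str = "one-minus-f",
    extra_bipartitions=None,
    max_redraw: int = 1000,
    collect_splits: bool = False,
) -> tuple[dendropy.Tree, SupportTable]:
    """Point-estimate NJ tree plus locus-bootstrap support.

    Loci (columns) are resampled with replacement to the original count;
    support for each internal bipartition of the point-estimate tree — and
    any caller-supplied query bipartitions on the same leaf set — is the
    percentage of pseudoreplicate trees containing it. Pseudoreplicates
    with an undefined pairwise distance are redrawn and counted.
    """
    if matrix.n_samples < 3:
        raise AflPhyloError("bootstrap requires at least 3 samples")
    if n_pseudoreplicates < 1:
        raise AflPhyloError("n_pseudoreplicates must be >= 1")
    from .distance import distance_matrix  # local import avoids cycle at module load

    dm = distance_matrix(matrix, level="sample", transform=transform)
    tree = neighbor_joining(dm)
    queries = set(tree_bipartitions(tree))
    if extra_bipartitions:
        queries |= {bp for bp in extra_bipartitions}
    counts = {bp: 0 for bp in queries}
    labels = list(matrix.sample_ids)
    calls = matrix.calls
    n_loci = matrix.n_loci
    rng = np.random.default_rng(seed)
    n_redrawn = 0
    done = 0
    all_splits: list[set] | None = [] if collect_splits else None
    while done < n_pseudoreplicates:
        idx = rng.integers(0, n_loci, size=n_loci)
        sub = calls[:, idx]
        try:
            f = _pairwise_f(sub)
            d = np.asarray(_apply_transform(f, transform), dtype=float)
        except UndefinedDistanceError:
            n_redrawn += 1
            if n_redrawn > max_redraw:
                raise AflPhyloError("too many undefined-distance pseudoreplicates")
            continue
        np.fill_diagonal(d, 0.0)
        np.maximum(d, 0.0, out=d)
        splits = _nj_splits(d, labels)
        for bp in splits & queries:
            counts[bp] += 1
        if all_splits is not None:
            all_splits.append(splits)
        done += 1
    entries = {bp: 100.0 * c / n_pseudoreplicates for bp, c in counts.items()}
    return tree, SupportTable(entries, n_pseudoreplicates, n_redrawn, all_splits)
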