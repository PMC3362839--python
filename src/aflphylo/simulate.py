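"""Synthetic AFLP-like data with ground truth.

Generates pure-birth species trees, two-state presence/absence characters
evolved down the tree, optional planted hybrid species built as per-locus
mosaics of two parental consensus profiles, and noisy peak-height
renderings with replicate profiles — everything downstream stages need as
a ground-truth test harness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import dendropy
import numpy as np

from .data import BinaryCharacterMatrix, PeakHeightTable
from .errors import AflPhyloError
from .trees import leaf_labels

__all__ = [
    "SimulationConfig",
    "HybridSpec",
    "GroundTruth",
    "simulate_species_tree",
    "simulate_binary_characters",
    "plant_hybrid",
    "synthesize_peak_heights",
    "simulate_dataset",
]

# peak-height emission constants (two-component signal/baseline model)
SIGNAL_MEAN = 1000.0
BASELINE_MEAN = 50.0


@dataclass
class HybridSpec:
    """A planted hybrid: per-locus mosaic of two parental species consensi."""

    label: str
    parent_a: str
    parent_b: str
    mixing_proportion: float = 0.5
    n_individuals: int | None = None  # default: match parent_a's sample count
    # independent per-locus mosaic per individual (a segregating hybrid swarm)
    # versus one shared mosaic for the whole species (a clonal F1-like taxon)
    per_individual: bool = True
    # extra per-individual flip rate on top of the mosaic, emulating
    # segregating variation beyond the two parental consensi
    noise_rate: float = 0.0
    # draw the origin vector so that the loci at which the parents differ
    # split exactly per mixing_proportion (an F1-like balanced mosaic),
    # rather than independently per locus
    balanced: bool = False

    def validate(self) -> None:
        if self.parent_a == self.parent_b:
            raise AflPhyloError("hybrid parents must be distinct species")
        if not 0.0 <= self.mixing_proportion <= 1.0:
            raise AflPhyloError("mixing_proportion must be in [0, 1]")
        if not 0.0 <= self.noise_rate <= 1.0:
            raise AflPhyloError("noise_rate must be in [0, 1]")


@dataclass
class SimulationConfig:
    n_species: int = 10
    individuals_per_species: int = 4
    n_loci: int = 600
    birth_rate: float = 1.0
    tree_height: float = 0.5
    presence_freq: float | None = 0.29
    gain_loss_ratio: float | None = None
    polymorphism_rate: float = 0.01
    hybrid_specs: list[HybridSpec] = field(default_factory=list)
    n_replicate_samples: int = 0
    noise_sd: float = 0.0
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.presence_freq is None:
            if self.gain_loss_ratio is None:
                raise AflPhyloError("one of presence_freq / gain_loss_ratio is required")
            # stationary presence frequency implied by the gain:loss rate ratio
            self.presence_freq = self.gain_loss_ratio / (1.0 + self.gain_loss_ratio)
        if not 0.0 < self.presence_freq < 1.0:
            raise AflPhyloError(
                "presence_freq must lie strictly inside (0, 1); the boundary "
                "values admit no polymorphic loci"
            )
        if self.gain_loss_ratio is None:
            self.gain_loss_ratio = self.presence_freq / (1.0 - self.presence_freq)
        for name in ("n_species", "individuals_per_species", "n_loci"):
            if getattr(self, name) < 1:
                raise AflPhyloError(f"{name} must be >= 1")
        for name in ("polymorphism_rate", "dropout_rate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise AflPhyloError(f"{name} must be in [0, 1]")
        if self.noise_sd < 0:
            raise AflPhyloError("noise_sd must be >= 0")
        if self.n_replicate_samples < 0:
            raise AflPhyloError("n_replicate_samples must be >= 0")
        hybrid_labels = {h.label for h in self.hybrid_specs}
        for h in self.hybrid_specs:
            h.validate()
            for parent in (h.parent_a, h.parent_b):
                if parent in hybrid_labels:
                    raise AflPhyloError("hybrid parents must be non-hybrid species")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """What the generator actually did, for parameter-recovery tests."""

    species_tree: dendropy.Tree
    true_matrix: BinaryCharacterMatrix
    # species -> (parent_a, parent_b, proportion, per-locus origin vector;
    # origin[i] == 1 means locus i was copied from parent_a)
    hybrid_assignments: dict[str, tuple[str, str, float, np.ndarray]] = field(
        default_factory=dict
    )
    species_states: np.ndarray | None = None  # (n_species, n_loci) pre-polymorphism

    def to_json(self) -> str:
        payload = {
            "species_tree": self.species_tree.as_string(schema="newick").strip(),
            "sample_ids": self.true_matrix.sample_ids,
            "species_map": self.true_matrix.species_map,
            "hybrid_assignments": {
                sp: {
                    "parent_a": pa,
                    "parent_b": pb,
                    "proportion": prop,
                    "origin": np.asarray(origin).astype(int).tolist(),
                }
                for sp, (pa, pb, prop, origin) in self.hybrid_assignments.items()
            },
        }
        return json.dumps(payload, indent=1)


def _species_labels(n: int) -> list[str]:
    width = max(2, len(str(n)))
    return [f"sp{i + 1:0{width}d}" for i in range(n)]


def simulate_species_tree(
    n_species: int,
    birth_rate: float = 1.0,
    tree_height: float = 0.5,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    labels: list[str] | None = None,
) -> dendropy.Tree:
    """Ultrametric pure-birth (Yule) tree rescaled to ``tree_height``.

    Lineages split at exponential waiting times with total rate
    ``k * birth_rate``; the splitting lineage is uniform among the ``k``
    extant ones. All root-to-tip paths equal ``tree_height`` exactly.
    """
    if n_species < 3:
        raise AflPhyloError("n_species must be >= 3")
    if birth_rate <= 0 or tree_height <= 0:
        raise AflPhyloError("birth_rate and tree_height must be positive")
    if rng is None:
        rng = np.random.default_rng(seed)
    labels = labels or _species_labels(n_species)
    if len(labels) != n_species:
        raise AflPhyloError("labels length must equal n_species")

    taxon_namespace = dendropy.TaxonNamespace(labels)
    root = dendropy.Node()
    depth = {id(root): 0.0}
    tips = [root]
    t = 0.0
    while len(tips) < n_species:
        k = len(tips)
        t += rng.exponential(1.0 / (k * birth_rate))
        pick = int(rng.integers(0, k))
        parent = tips.pop(pick)
        depth[id(parent)] = t
        for _ in range(2):
            child = dendropy.Node()
            parent.add_child(child)
            tips.append(child)
    t_present = t + rng.exponential(1.0 / (n_species * birth_rate))
    # height is measured from the root's first split, not from time zero
    scale = tree_height / (t_present - depth[id(root)])
    order = rng.permutation(n_species)
    for i, tip in enumerate(tips):
        tip.taxon = taxon_namespace.get_taxon(labels[order[i]])
        depth[id(tip)] = t_present
    tree = dendropy.Tree(taxon_namespace=taxon_namespace)
    tree.seed_node = root
    for node in tree.preorder_node_iter():
        if node.parent_node is not None:
            node.edge.length = (depth[id(node)] - depth[id(node.parent_node)]) * scale
    tree.is_rooted = True
    return tree


def _two_state_transition(parent_states: np.ndarray, t: float, pi1: float,
                          rng: np.random.Generator) -> np.ndarray:
    """Evolve 0/1 states along one branch of length t (expected substitutions)."""
    pi0 = 1.0 - pi1
    mu = 1.0 / (2.0 * pi0 * pi1)  # normalises expected rate to 1 per unit length
    e = np.exp(-mu * t)
    # P(child=1 | parent)
    p1 = np.where(parent_states == 1, pi1 + pi0 * e, pi1 * (1.0 - e))
    return (rng.random(parent_states.shape) < p1).astype(np.int8)


def _simulate_species_states(
    tree: dendropy.Tree, n_loci: int, pi1: float, rng: np.random.Generator
) -> tuple[np.ndarray, list[str]]:
    """Per-species 0/1 states for ``n_loci`` characters evolved down ``tree``."""
    states: dict[int, np.ndarray] = {}
    leaves: list[tuple[str, np.ndarray]] = []
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            states[id(node)] = (rng.random(n_loci) < pi1).astype(np.int8)
        else:
            t = node.edge.length or 0.0
            states[id(node)] = _two_state_transition(states[id(node.parent_node)], t, pi1, rng)
        if node.is_leaf():
            leaves.append((node.taxon.label, states[id(node)]))
    leaves.sort(key=lambda kv: kv[0])
    labels = [lab for lab, _ in leaves]
    return np.stack([s for _, s in leaves]), labels


def simulate_binary_characters(
    tree: dendropy.Tree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    require_polymorphic: bool = True,
    max_batches: int = 200,
) -> tuple[BinaryCharacterMatrix, GroundTruth]:
    """Simulate presence/absence characters for every individual.

    Each locus evolves as a stationary two-state Markov chain down the
    species tree; individuals copy their species' state and flip it
    independently with ``polymorphism_rate``. When ``require_polymorphic``
    (the default) loci monomorphic across all samples are discarded and
    re-drawn until exactly ``n_loci`` polymorphic loci exist.
    """
    pi1 = float(config.presence_freq)
    if not 0.0 < pi1 < 1.0:
        raise AflPhyloError("presence_freq must lie strictly inside (0, 1)")
    species = leaf_labels(tree)
    if len(species) != config.n_species:
        raise AflPhyloError("tree leaf count does not match config.n_species")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    zero_tree = all((n.edge.length or 0.0) == 0.0
                    for n in tree.preorder_node_iter() if n.parent_node is not None)
    if require_polymorphic and zero_tree and config.polymorphism_rate == 0.0:
        raise AflPhyloError(
            "degenerate simulation: zero-length tree with polymorphism_rate=0 "
            "cannot produce polymorphic loci"
        )

    k = config.individuals_per_species
    sample_ids = [f"{sp}_{i + 1}" for sp in species for i in range(k)]
    species_map = {f"{sp}_{i + 1}": sp for sp in species for i in range(k)}

    kept_cols: list[np.ndarray] = []
    kept_species_cols: list[np.ndarray] = []
    n_needed = config.n_loci
    for _ in range(max_batches):
        batch = max(n_needed, 64)
        sp_states, sp_labels = _simulate_species_states(tree, batch, pi1, rng)
        ind = np.repeat(sp_states, k, axis=0)  # rows follow sorted species order
        flips = rng.random(ind.shape) < config.polymorphism_rate
        ind = np.where(flips, 1 - ind, ind).astype(np.int8)
        if require_polymorphic:
            colsum = ind.sum(axis=0)
            ok = (colsum > 0) & (colsum < ind.shape[0])
        else:
            ok = np.ones(ind.shape[1], dtype=bool)
        take = np.flatnonzero(ok)[:n_needed]
        if take.size:
            kept_cols.append(ind[:, take])
            kept_species_cols.append(sp_states[:, take])
            n_needed -= take.size
        if n_needed == 0:
            break
    else:
        raise AflPhyloError(
            "could not obtain enough polymorphic loci; the configuration is too "
            "close to degeneracy (check tree height / polymorphism_rate)"
        )

    calls = np.concatenate(kept_cols, axis=1)
    sp_matrix = np.concatenate(kept_species_cols, axis=1)
    # rows of `ind` follow sorted species labels; sample_ids follow leaf order —
    # align sample rows with the sorted-species stacking used above
    sorted_ids = [f"{sp}_{i + 1}" for sp in sorted(species) for i in range(k)]
    locus_ids = [f"L{j + 1:04d}" for j in range(config.n_loci)]
    matrix = BinaryCharacterMatrix(calls, sorted_ids, locus_ids, species_map)
    if sorted_ids != sample_ids:
        matrix = matrix.subset_samples(sample_ids)
    truth = GroundTruth(
        species_tree=tree,
        true_matrix=matrix,
        hybrid_assignments={},
        species_states=sp_matrix,
    )
    return matrix, truth


def plant_hybrid(
    matrix: BinaryCharacterMatrix,
    ground_truth: GroundTruth,
    hybrid_spec: HybridSpec,
    seed: int,
) -> tuple[BinaryCharacterMatrix, GroundTruth]:
    """Replace (or add) a species with a mosaic of two parental consensi.

    Per locus, the hybrid takes parent A's consensus state with probability
    ``mixing_proportion``, else parent B's. With ``per_individual`` (the
    default) every hybrid individual draws its own origin vector, like a
    segregating hybrid swarm — this is what gives the downstream homoplasy
    test its signal, since the individuals then straddle the parental
    clades. With ``per_individual=False`` the whole species shares one
    mosaic. Rows of other species are untouched. The recorded
    parent-of-origin vector is the first individual's.
    """
    hybrid_spec.validate()
    for parent in (hybrid_spec.parent_a, hybrid_spec.parent_b):
        if parent not in matrix.species():
            raise AflPhyloError(f"parent species {parent!r} not in matrix")
        if parent in ground_truth.hybrid_assignments:
            raise AflPhyloError(f"parent species {parent!r} is itself a hybrid")
    if hybrid_spec.label in (hybrid_spec.parent_a, hybrid_spec.parent_b):
        raise AflPhyloError("hybrid label cannot equal a parent label")

    rng = np.random.default_rng(seed)
    cons_a = matrix.species_consensus(hybrid_spec.parent_a)
    cons_b = matrix.species_consensus(hybrid_spec.parent_b)

    calls = matrix.calls.copy()
    sample_ids = list(matrix.sample_ids)
    species_map = dict(matrix.species_map)
    existing = [i for i, s in enumerate(sample_ids) if species_map.get(s) == hybrid_spec.label]
    if existing:
        n_ind = len(existing)
    else:
        n_ind = hybrid_spec.n_individuals
        if n_ind is None:
            n_ind = len(matrix.rows_for_species(hybrid_spec.parent_a))

    n_draws = n_ind if hybrid_spec.per_individual else 1
    if hybrid_spec.balanced:
        # exact split of the parent-informative loci; uninformative loci are
        # identical under either parent, so their origin label is arbitrary
        origins = np.zeros((n_draws, matrix.n_loci), dtype=np.int8)
        informative = np.flatnonzero(cons_a != cons_b)
        k = int(round(hybrid_spec.mixing_proportion * informative.size))
        for i in range(n_draws):
            take = rng.choice(informative, size=k, replace=False)
            origins[i, take] = 1
    else:
        origins = (rng.random((n_draws, matrix.n_loci))
                   < hybrid_spec.mixing_proportion).astype(np.int8)
    mosaics = np.where(origins == 1, cons_a[None, :], cons_b[None, :]).astype(np.int8)
    if not hybrid_spec.per_individual:
        mosaics = np.tile(mosaics, (n_ind, 1))
    if hybrid_spec.noise_rate > 0:
        flips = rng.random(mosaics.shape) < hybrid_spec.noise_rate
        mosaics = np.where(flips, 1 - mosaics, mosaics).astype(np.int8)
    origin = origins[0]

    if existing:
        calls[existing] = mosaics
    else:
        new_ids = [f"{hybrid_spec.label}_{i + 1}" for i in range(n_ind)]
        calls = np.vstack([calls, mosaics])
        sample_ids.extend(new_ids)
        species_map.update({s: hybrid_spec.label for s in new_ids})

    new_matrix = BinaryCharacterMatrix(calls, sample_ids, list(matrix.locus_ids), species_map)
    assignments = dict(ground_truth.hybrid_assignments)
    assignments[hybrid_spec.label] = (
        hybrid_spec.parent_a,
        hybrid_spec.parent_b,
        hybrid_spec.mixing_proportion,
        origin,
    )
    truth = GroundTruth(
        species_tree=ground_truth.species_tree,
        true_matrix=new_matrix,
        hybrid_assignments=assignments,
        species_states=ground_truth.species_states,
    )
    return new_matrix, truth


def synthesize_peak_heights(
    matrix: BinaryCharacterMatrix,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> PeakHeightTable:
    """Render binary calls as noisy fluorescence intensities.

    Presence emits from a high-intensity signal component, absence from a
    low baseline; both Gaussian with ``noise_sd``, truncated at zero. True
    peaks drop to baseline with ``dropout_rate``. The first
    ``n_replicate_samples`` samples get duplicate profiles re-rendered with
    fresh noise and entered in the replicate pairing map.
    """
    if config.dropout_rate >= 1.0:
        raise AflPhyloError("dropout_rate must be < 1")
    if config.n_replicate_samples > matrix.n_samples:
        raise AflPhyloError("more replicate samples requested than samples available")
    if rng is None:
        rng = np.random.default_rng(config.seed + 1)

    def render(rows: np.ndarray) -> np.ndarray:
        dropped = rows & (rng.random(rows.shape) < config.dropout_rate).astype(np.int8)
        on = (rows == 1) & (dropped == 0)
        means = np.where(on, SIGNAL_MEAN, BASELINE_MEAN)
        return np.maximum(means + rng.normal(0.0, config.noise_sd, rows.shape)
                          if config.noise_sd > 0 else means.astype(float), 0.0)

    heights = render(matrix.calls)
    sample_ids = list(matrix.sample_ids)
    pairs: list[tuple[str, str]] = []
    if config.n_replicate_samples:
        rep_rows = render(matrix.calls[: config.n_replicate_samples])
        rep_ids = [f"{s}__rep" for s in sample_ids[: config.n_replicate_samples]]
        heights = np.vstack([heights, rep_rows])
        pairs = list(zip(sample_ids[: config.n_replicate_samples], rep_ids))
        sample_ids = sample_ids + rep_ids

    bins = np.round(np.linspace(50.0, 500.0, matrix.n_loci), 4)
    return PeakHeightTable(heights, sample_ids, bins, pairs, dict(matrix.species_map))


def simulate_dataset(config: SimulationConfig):
    """Full generator: tree -> characters -> hybrids -> peaks.

    Returns ``(peaks, matrix, truth)``. All randomness derives from
    ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    tree = simulate_species_tree(
        config.n_species, config.birth_rate, config.tree_height, rng=rng
    )
    matrix, truth = simulate_binary_characters(tree, config, rng=rng)
    for i, spec in enumerate(config.hybrid_specs):
        matrix, truth = plant_hybrid(matrix, truth, spec, seed=config.seed + 104729 * (i + 1))
    peaks = synthesize_peak_heights(matrix, config, rng=rng)
    return peaks, matrix, truth
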