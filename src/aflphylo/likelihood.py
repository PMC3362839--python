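"""Two-state (restriction-site style) likelihood machinery on fixed topologies.

Felsenstein pruning for a reversible 0/1 Markov process with stationary
frequencies (pi0, pi1), optional ascertainment conditioning that excludes
the unobservable all-absent pattern, coordinate-ascent branch-length
optimisation, SH/RELL topology testing, and a harmonic-mean marginal
likelihood with Bayes-factor comparison.

Branch lengths are in expected substitutions per site: the rate matrix is
normalised so one unit of length produces one expected state change at
stationarity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import logsumexp

from .data import BinaryCharacterMatrix
from .errors import AflPhyloError, NumericalDegeneracyError

__all__ = [
    "BinaryModel",
    "SiteLikelihoods",
    "TopologyTestResult",
    "McmcSettings",
    "HarmonicMeanEstimate",
    "estimate_state_frequencies",
    "site_log_likelihood",
    "matrix_log_likelihood",
    "optimize_branch_lengths",
    "sh_test",
    "marginal_likelihood_harmonic",
    "bayes_factor",
]

_BL_LO = 1e-9
_BL_HI = 50.0


@dataclass(frozen=True)
class BinaryModel:
    pi0: float
    pi1: float
    conditioning: str = "none"  # "none" | "noabsencesites"
    rate_scale: float = 1.0

    def __post_init__(self) -> None:
        if not (self.pi0 > 0 and self.pi1 > 0):
            raise AflPhyloError("state frequencies must be positive")
        if abs(self.pi0 + self.pi1 - 1.0) > 1e-9:
            raise AflPhyloError("state frequencies must sum to 1")
        if self.conditioning not in ("none", "noabsencesites"):
            raise AflPhyloError("conditioning must be 'none' or 'noabsencesites'")
        if self.rate_scale <= 0:
            raise AflPhyloError("rate_scale must be positive")

    @property
    def mu(self) -> float:
        """Off-diagonal rate multiplier normalising the expected rate to rate_scale."""
        return self.rate_scale / (2.0 * self.pi0 * self.pi1)


def estimate_state_frequencies(
    matrix: BinaryCharacterMatrix, conditioning: str = "none"
) -> BinaryModel:
    """Empirical point estimate: pi1 = global fraction of 1-entries."""
    if matrix.n_loci == 0 or matrix.n_samples == 0:
        raise AflPhyloError("empty matrix")
    pi1 = float(matrix.calls.mean())
    if pi1 in (0.0, 1.0):
        raise AflPhyloError("degenerate matrix: all-zero or all-one")
    return BinaryModel(pi0=1.0 - pi1, pi1=pi1, conditioning=conditioning)


@dataclass
class SiteLikelihoods:
    topology_id: str
    per_locus_loglik: np.ndarray  # nats, conditioning already applied
    total_loglik: float
    conditioning_correction: float  # log(1 - P(all-absent)) or 0.0
    converged: bool = True

    def __post_init__(self) -> None:
        self.per_locus_loglik = np.asarray(self.per_locus_loglik, dtype=float)
        if not np.isclose(self.total_loglik, self.per_locus_loglik.sum()):
            raise AflPhyloError("total_loglik does not match per-locus sum")


# ---------------------------------------------------------------------------
# flattened tree + pruning core
# ---------------------------------------------------------------------------

class _FlatTree:
    """Postorder array view of a dendropy tree for vectorised pruning."""

    def __init__(self, tree: dendropy.Tree):
        self.tree = tree
        nodes = list(tree.postorder_node_iter())
        self.index = {id(n): i for i, n in enumerate(nodes)}
        self.nodes = nodes
        self.n_nodes = len(nodes)
        self.children: list[list[int]] = []
        self.lengths = np.zeros(self.n_nodes)
        self.leaf_labels: list[str] = []
        self.leaf_index: list[int] = []
        for i, n in enumerate(nodes):
            self.children.append([self.index[id(c)] for c in n.child_nodes()])
            if n.parent_node is not None:
                self.lengths[i] = float(n.edge.length or 0.0)
            if n.is_leaf():
                self.leaf_labels.append(n.taxon.label)
                self.leaf_index.append(i)
        self.root = self.n_nodes - 1
        # edges eligible for optimisation: every node with a parent
        self.edge_nodes = [i for i, n in enumerate(nodes) if n.parent_node is not None]

    def write_back(self) -> dendropy.Tree:
        for i, n in enumerate(self.nodes):
            if n.parent_node is not None:
                n.edge.length = float(self.lengths[i])
        return self.tree


def _transition_matrices(lengths: np.ndarray, model: BinaryModel) -> np.ndarray:
    e = np.exp(-model.mu * np.asarray(lengths))
    p = np.empty(np.shape(lengths) + (2, 2))
    p[..., 0, 0] = model.pi0 + model.pi1 * e
    p[..., 0, 1] = model.pi1 * (1.0 - e)
    p[..., 1, 0] = model.pi0 * (1.0 - e)
    p[..., 1, 1] = model.pi1 + model.pi0 * e
    return p


def _pattern_logliks(flat: _FlatTree, model: BinaryModel, patterns: np.ndarray) -> np.ndarray:
    """Unconditioned log-likelihood per pattern.

    ``patterns``: (n_patterns, n_leaves) 0/1 array, leaf order matching
    ``flat.leaf_labels``.
    """
    n_pat = patterns.shape[0]
    pmats = _transition_matrices(flat.lengths, model)
    partial = [None] * flat.n_nodes
    logscale = np.zeros(n_pat)
    leaf_pos = {node_i: k for k, node_i in enumerate(flat.leaf_index)}
    for i in range(flat.n_nodes):
        if not flat.children[i]:
            states = patterns[:, leaf_pos[i]]
            lk = np.zeros((n_pat, 2))
            lk[np.arange(n_pat), states] = 1.0
            partial[i] = lk
        else:
            lk = np.ones((n_pat, 2))
            for c in flat.children[i]:
                lk = lk * (partial[c] @ pmats[c].T)
                partial[c] = None
            smax = lk.max(axis=1)
            smax[smax == 0] = 1.0
            lk /= smax[:, None]
            logscale += np.log(smax)
            partial[i] = lk
    pi = np.array([model.pi0, model.pi1])
    root_lk = partial[flat.root] @ pi
    with np.errstate(divide="ignore"):
        return np.log(root_lk) + logscale


def _all_absent_loglik(flat: _FlatTree, model: BinaryModel) -> float:
    zero = np.zeros((1, len(flat.leaf_labels)), dtype=np.int8)
    return float(_pattern_logliks(flat, model, zero)[0])


def _conditioning_term(flat: _FlatTree, model: BinaryModel) -> float:
    """log(1 - P(all-absent)); raises when the correction degenerates."""
    l0 = np.exp(_all_absent_loglik(flat, model))
    if l0 >= 1.0 - 1e-12:
        raise NumericalDegeneracyError(
            "P(all-absent) ~ 1: noabsencesites conditioning is numerically degenerate"
        )
    return float(np.log1p(-l0))


def _leaf_ordered_patterns(flat: _FlatTree, matrix: BinaryCharacterMatrix) -> np.ndarray:
    pos = {s: i for i, s in enumerate(matrix.sample_ids)}
    missing = [lab for lab in flat.leaf_labels if lab not in pos]
    if missing or len(flat.leaf_labels) != matrix.n_samples:
        raise AflPhyloError(
            f"tree leaves and matrix samples differ (missing from matrix: {missing})"
        )
    rows = [pos[lab] for lab in flat.leaf_labels]
    return matrix.calls[rows].T.copy()  # (n_loci, n_leaves)


def site_log_likelihood(tree: dendropy.Tree, model: BinaryModel, pattern) -> float:
    """Log-probability of one 0/1 leaf pattern (leaf order = sorted labels).

    The process is reversible, so the value is invariant to root placement.
    Conditioning is *not* applied here; see :func:`matrix_log_likelihood`.
    """
    flat = _FlatTree(tree)
    pattern = np.asarray(pattern, dtype=np.int8)
    if pattern.shape != (len(flat.leaf_labels),):
        raise AflPhyloError("pattern length must equal the number of leaves")
    state = dict(zip(sorted(flat.leaf_labels), pattern))
    arranged = np.array([[state[lab] for lab in flat.leaf_labels]], dtype=np.int8)
    return float(_pattern_logliks(flat, model, arranged)[0])


def matrix_log_likelihood(
    tree: dendropy.Tree,
    model: BinaryModel,
    matrix: BinaryCharacterMatrix,
    topology_id: str = "tree",
) -> SiteLikelihoods:
    """Per-locus and total log-likelihood, with optional conditioning.

    Under ``noabsencesites`` each site likelihood is divided by
    ``1 - P(all-absent)`` evaluated on the same tree and model.
    """
    flat = _FlatTree(tree)
    pats = _leaf_ordered_patterns(flat, matrix)
    uniq, inverse = np.unique(pats, axis=0, return_inverse=True)
    lnl_uniq = _pattern_logliks(flat, model, uniq)
    per_locus = lnl_uniq[inverse]
    correction = 0.0
    if model.conditioning == "noabsencesites":
        correction = _conditioning_term(flat, model)
        per_locus = per_locus - correction
    return SiteLikelihoods(
        topology_id=topology_id,
        per_locus_loglik=per_locus,
        total_loglik=float(per_locus.sum()),
        conditioning_correction=correction,
    )


# ---------------------------------------------------------------------------
# branch-length optimisation
# ---------------------------------------------------------------------------

def _total_loglik_flat(flat: _FlatTree, model: BinaryModel,
                       uniq: np.ndarray, counts: np.ndarray) -> float:
    lnl = _pattern_logliks(flat, model, uniq)
    total = float(counts @ lnl)
    if model.conditioning == "noabsencesites":
        total -= counts.sum() * _conditioning_term(flat, model)
    return total


def optimize_branch_lengths(
    topology: dendropy.Tree,
    model: BinaryModel,
    matrix: BinaryCharacterMatrix,
    tol: float = 1e-6,
    max_sweeps: int = 30,
    topology_id: str = "tree",
) -> tuple[dendropy.Tree, SiteLikelihoods]:
    """Maximise the (possibly conditioned) likelihood over branch lengths.

    Coordinate ascent: each edge in turn is optimised by bounded Brent
    search; sweeps repeat until the total improves by less than ``tol``.
    The input topology is not modified. Non-convergence is flagged on the
    returned :class:`SiteLikelihoods` rather than raised.
    """
    tree = topology.clone(depth=1)
    flat = _FlatTree(tree)
    pats = _leaf_ordered_patterns(flat, matrix)
    uniq, inverse = np.unique(pats, axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=uniq.shape[0]).astype(float)
    # start from strictly positive lengths
    flat.lengths[flat.edge_nodes] = np.maximum(flat.lengths[flat.edge_nodes], 0.05)

    current = _total_loglik_flat(flat, model, uniq, counts)
    # log-spaced scan brackets the optimum before Brent refinement; a naive
    # bounded search can stall on the saturation plateau at large lengths
    scan = np.geomspace(1e-6, _BL_HI, 13)
    converged = False
    for _ in range(max_sweeps):
        before = current
        for e in flat.edge_nodes:
            def neg(x, e=e):
                flat.lengths[e] = x
                return -_total_loglik_flat(flat, model, uniq, counts)

            pts = np.unique(np.append(scan, flat.lengths[e]))
            vals = np.array([neg(x) for x in pts])
            k = int(np.argmin(vals))
            lo = pts[k - 1] if k > 0 else _BL_LO
            hi = pts[k + 1] if k < len(pts) - 1 else _BL_HI
            res = minimize_scalar(neg, bounds=(lo, hi), method="bounded",
                                  options={"xatol": 1e-10})
            if res.fun <= vals[k]:
                flat.lengths[e] = float(res.x)
                current = -float(res.fun)
            else:
                flat.lengths[e] = float(pts[k])
                current = -float(vals[k])
        if current - before < tol:
            converged = True
            break
    out_tree = flat.write_back()
    lnl_uniq = _pattern_logliks(flat, model, uniq)
    per_locus = lnl_uniq[inverse]
    correction = 0.0
    if model.conditioning == "noabsencesites":
        correction = _conditioning_term(flat, model)
        per_locus = per_locus - correction
    site = SiteLikelihoods(
        topology_id=topology_id,
        per_locus_loglik=per_locus,
        total_loglik=float(per_locus.sum()),
        conditioning_correction=correction,
        converged=converged,
    )
    return out_tree, site


# ---------------------------------------------------------------------------
# SH test (RELL)
# ---------------------------------------------------------------------------

@dataclass
class TopologyTestResult:
    sh_pvalues: dict[str, float]
    deltas: dict[str, float]  # lnL shortfall vs the best topology
    bf_2ln: dict[tuple[str, str], float] = field(default_factory=dict)
    bf_verdict: dict[tuple[str, str], str] = field(default_factory=dict)
    site_likelihoods: dict[str, SiteLikelihoods] = field(default_factory=dict)


def sh_test(
    matrix: BinaryCharacterMatrix,
    topologies: dict[str, dendropy.Tree],
    model: BinaryModel,
    n_rell: int = 1000,
    seed: int = 0,
    opt_tol: float = 1e-6,
) -> TopologyTestResult:
    """Shimodaira-Hasegawa test with full per-topology optimisation and RELL.

    Branch lengths are re-optimised for every candidate topology; per-site
    log-likelihoods are bootstrapped (RELL), each topology's replicate sums
    are centred by their own mean, and the p-value for topology ``t`` is
    the fraction of replicates in which the centred best-vs-t gap reaches
    the observed gap.
    """
    if len(topologies) < 2:
        raise AflPhyloError("sh_test needs at least two topologies")
    leafsets = {name: frozenset(lf.taxon.label for lf in t.leaf_node_iter())
                for name, t in topologies.items()}
    ref = next(iter(leafsets.values()))
    for name, ls in leafsets.items():
        if ls != ref:
            raise AflPhyloError(f"topology {name!r} has a mismatched leaf set")
    names = list(topologies)
    sites: dict[str, SiteLikelihoods] = {}
    for name in names:
        _, site = optimize_branch_lengths(topologies[name], model, matrix,
                                          tol=opt_tol, topology_id=name)
        sites[name] = site
    per = np.stack([sites[name].per_locus_loglik for name in names])  # (T, L)
    totals = per.sum(axis=1)
    best = totals.max()
    obs_delta = best - totals

    rng = np.random.default_rng(seed)
    n_loci = per.shape[1]
    rell = np.empty((len(names), n_rell))
    for b in range(n_rell):
        idx = rng.integers(0, n_loci, size=n_loci)
        rell[:, b] = per[:, idx].sum(axis=1)
    centered = rell - rell.mean(axis=1, keepdims=True)
    gaps = centered.max(axis=0)[None, :] - centered  # (T, B)
    pvals = (gaps >= obs_delta[:, None]).mean(axis=1)
    return TopologyTestResult(
        sh_pvalues={name: float(p) for name, p in zip(names, pvals)},
        deltas={name: float(d) for name, d in zip(names, obs_delta)},
        site_likelihoods=sites,
    )


# ---------------------------------------------------------------------------
# harmonic-mean marginal likelihood + Bayes factors
# ---------------------------------------------------------------------------

@dataclass
class McmcSettings:
    n_generations: int = 20000
    burnin_frac: float = 0.5
    sample_every: int = 10
    prior_mean: float = 0.1   # exponential prior on each branch length
    proposal_lambda: float = 1.5  # multiplier-move window
    n_runs: int = 2

    def __post_init__(self) -> None:
        if self.n_generations < 1:
            raise AflPhyloError("n_generations must be >= 1")
        if not 0.0 <= self.burnin_frac < 1.0:
            raise AflPhyloError("burnin_frac must be in [0, 1)")
        if self.prior_mean <= 0:
            raise AflPhyloError("prior_mean must be positive")


@dataclass
class HarmonicMeanEstimate:
    """Per-run harmonic-mean lnL estimates (known to be unstable; reported as-is).

    The run-to-run spread is the practical diagnostic; ``warning`` is set
    when a chain's acceptance rate leaves (0.05, 0.8).
    """

    per_run: list[float]
    acceptance_rates: list[float]
    warning: bool

    @property
    def estimate(self) -> float:
        return float(np.mean(self.per_run))


def marginal_likelihood_harmonic(
    topology: dendropy.Tree,
    model: BinaryModel,
    matrix: BinaryCharacterMatrix,
    settings: McmcSettings | None = None,
    seed: int = 0,
) -> HarmonicMeanEstimate:
    """Harmonic-mean estimate of the marginal log-likelihood on a fixed topology.

    Branch lengths are sampled by single-branch multiplier Metropolis moves
    under independent exponential priors; the harmonic mean of the sampled
    likelihoods (after burn-in) estimates the marginal likelihood.
    """
    settings = settings or McmcSettings()
    flat = _FlatTree(topology.clone(depth=1))
    pats = _leaf_ordered_patterns(flat, matrix)
    uniq, inverse = np.unique(pats, axis=0, return_inverse=True)
    counts = np.bincount(inverse, minlength=uniq.shape[0]).astype(float)
    n_edges = len(flat.edge_nodes)

    per_run: list[float] = []
    acc_rates: list[float] = []
    for run in range(settings.n_runs):
        rng = np.random.default_rng((seed, run))
        lengths = rng.exponential(settings.prior_mean, size=n_edges)
        flat.lengths[flat.edge_nodes] = lengths
        lnl = _total_loglik_flat(flat, model, uniq, counts)
        ln_prior = float(-np.sum(lengths) / settings.prior_mean)
        samples: list[float] = []
        n_acc = 0
        burn = int(settings.burnin_frac * settings.n_generations)
        for g in range(settings.n_generations):
            e = int(rng.integers(0, n_edges))
            old = lengths[e]
            factor = np.exp(settings.proposal_lambda * (rng.random() - 0.5))
            new = old * factor
            lengths[e] = new
            flat.lengths[flat.edge_nodes[e]] = new
            lnl_new = _total_loglik_flat(flat, model, uniq, counts)
            ln_prior_new = ln_prior - (new - old) / settings.prior_mean
            # Hastings ratio of the multiplier move is `factor`
            log_alpha = (lnl_new + ln_prior_new) - (lnl + ln_prior) + np.log(factor)
            if np.log(rng.random()) < log_alpha:
                lnl, ln_prior = lnl_new, ln_prior_new
                n_acc += 1
            else:
                lengths[e] = old
                flat.lengths[flat.edge_nodes[e]] = old
            if g >= burn and (g - burn) % settings.sample_every == 0:
                samples.append(lnl)
        if not samples:
            raise AflPhyloError("no post-burn-in samples; increase n_generations")
        arr = np.asarray(samples)
        ln_harmonic = float(np.log(len(arr)) - logsumexp(-arr))
        per_run.append(ln_harmonic)
        acc_rates.append(n_acc / settings.n_generations)
    warning = any(not (0.05 < a < 0.8) for a in acc_rates)
    return HarmonicMeanEstimate(per_run, acc_rates, warning)


def bayes_factor(ln_m1: float, ln_m2: float) -> tuple[float, str]:
    """2 x ln Bayes factor and the conventional strength verdict (> 10 = strong)."""
    if not (np.isfinite(ln_m1) and np.isfinite(ln_m2)):
        raise AflPhyloError("marginal log-likelihoods must be finite")
    value = 2.0 * (ln_m1 - ln_m2)
    return float(value), ("strong" if value > 10.0 else "not_strong")
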