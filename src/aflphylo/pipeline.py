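"""Pipeline driver chaining simulate -> score -> tree -> hybridtest -> topotest.

Each stage writes its artifacts plus a manifest entry (content hash, seed,
parameters). Stage toggles and parameter blocks come from a JSON config.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

from . import __version__
from .data import BinaryCharacterMatrix
from .errors import AflPhyloError
from .homoplasy import OutlierRule, run_homoplasy_excess
from .io import (
    file_sha256,
    read_binary_matrix,
    write_binary_matrix,
    write_json,
    write_peak_table,
    write_support_table,
    write_tree,
)
from .likelihood import (
    McmcSettings,
    bayes_factor,
    estimate_state_frequencies,
    marginal_likelihood_harmonic,
    sh_test,
)
from .nj import bootstrap_support
from .scoring import (
    GridSpec,
    drop_replicate_rows,
    estimate_mismatch_error_rate,
    filter_unique_loci,
    optimize_thresholds,
)
from .simulate import HybridSpec, SimulationConfig, simulate_dataset
from .trees import from_newick

log = logging.getLogger("aflphylo")

STAGES = ("simulate", "score", "tree", "hybridtest", "topotest")


@dataclass
class PipelineConfig:
    outdir: Path
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    simulate: dict = field(default_factory=dict)
    score: dict = field(default_factory=dict)
    tree: dict = field(default_factory=dict)
    hybridtest: dict = field(default_factory=dict)
    topotest: dict = field(default_factory=dict)

    @staticmethod
    def from_dict(cfg: dict, outdir=None) -> "PipelineConfig":
        unknown = set(cfg) - {"outdir", "seed", "stages", *STAGES}
        if unknown:
            raise AflPhyloError(f"unknown config keys: {sorted(unknown)}")
        out = Path(outdir or cfg.get("outdir", "aflphylo_out"))
        stages = tuple(cfg.get("stages", STAGES))
        bad = set(stages) - set(STAGES)
        if bad:
            raise AflPhyloError(f"unknown stages: {sorted(bad)}")
        return PipelineConfig(
            outdir=out,
            seed=int(cfg.get("seed", 0)),
            stages=stages,
            simulate=dict(cfg.get("simulate", {})),
            score=dict(cfg.get("score", {})),
            tree=dict(cfg.get("tree", {})),
            hybridtest=dict(cfg.get("hybridtest", {})),
            topotest=dict(cfg.get("topotest", {})),
        )


def _sim_config(block: dict, seed: int) -> SimulationConfig:
    block = dict(block)
    hybrids = [HybridSpec(**h) for h in block.pop("hybrid_specs", [])]
    block.setdefault("seed", seed)
    return SimulationConfig(hybrid_specs=hybrids, **block)


class _Manifest:
    def __init__(self, outdir: Path, seed: int):
        self.outdir = outdir
        self.entries: list[dict] = []
        self.seed = seed

    def add(self, path: Path, stage: str, params: dict) -> None:
        self.entries.append({
            "file": str(path.relative_to(self.outdir)),
            "sha256": file_sha256(path),
            "stage": stage,
            "seed": self.seed,
            "params": params,
            "version": __version__,
        })

    def write(self) -> None:
        write_json({"tool": "aflphylo", "version": __version__,
                    "entries": self.entries}, self.outdir / "manifest.json")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the enabled stages in order; returns a report bundle dict."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(outdir, config.seed)
    report: dict = {"stages": {}}
    matrix: BinaryCharacterMatrix | None = None
    peaks = None
    truth = None
    tree = None
    support = None

    for stage in config.stages:
        t0 = time.time()
        log.info("stage %s: start (seed=%d)", stage, config.seed)
        try:
            if stage == "simulate":
                sim_cfg = _sim_config(config.simulate, config.seed)
                peaks, matrix, truth = simulate_dataset(sim_cfg)
                write_peak_table(peaks, outdir / "peaks.tsv")
                write_binary_matrix(matrix, outdir / "true_matrix.tsv")
                write_binary_matrix(matrix, outdir / "true_matrix.nex",
                                    dialect="nexus-binary")
                write_tree(truth.species_tree, outdir / "species_tree.nwk")
                (outdir / "ground_truth.json").write_text(truth.to_json())
                for f in ("peaks.tsv", "true_matrix.tsv", "true_matrix.nex",
                          "species_tree.nwk", "ground_truth.json"):
                    manifest.add(outdir / f, stage, sim_cfg.to_dict())
                report["stages"][stage] = {"n_samples": matrix.n_samples,
                                           "n_loci": matrix.n_loci}
            elif stage == "score":
                if peaks is None:
                    from .io import read_peak_table
                    peaks = read_peak_table(config.score["peaks"])
                import numpy as _np

                grid_kwargs = {k: v for k, v in config.score.items()
                               if k in ("min_retained_frac",)}
                for key in ("retention_grid", "relative_grid", "absolute_grid"):
                    if key in config.score.get("grid", {}):
                        grid_kwargs[key] = _np.asarray(config.score["grid"][key],
                                                       dtype=float)
                if config.score.get("mode") in ("absolute", "relative"):
                    grid_kwargs["modes"] = (config.score["mode"],)
                grid = GridSpec(**grid_kwargs)
                thresholds, err = optimize_thresholds(peaks, grid)
                calls = drop_replicate_rows(
                    _call(peaks, thresholds), peaks.replicate_pairs)
                filt = filter_unique_loci(calls)
                matrix = filt.matrix
                write_binary_matrix(matrix, outdir / "scored_matrix.tsv")
                write_binary_matrix(matrix, outdir / "scored_matrix.nex",
                                    dialect="nexus-binary")
                write_json({
                    "thresholds": {
                        "retention_threshold": thresholds.retention_threshold,
                        "calling_mode": thresholds.calling_mode,
                        "calling_threshold": thresholds.calling_threshold,
                    },
                    "overall_error": err.overall_error,
                    "pair_mean_error": err.pair_mean_error,
                    "n_retained_loci": err.n_retained_loci,
                    "n_unique_loci": matrix.n_loci,
                }, outdir / "scoring_report.json")
                manifest.add(outdir / "scored_matrix.tsv", stage, {})
                manifest.add(outdir / "scoring_report.json", stage, {})
                report["stages"][stage] = {"overall_error": err.overall_error,
                                           "n_unique_loci": matrix.n_loci}
            elif stage == "tree":
                matrix = _need_matrix(matrix, config.tree)
                n_boot = int(config.tree.get("bootstrap", 1000))
                transform = config.tree.get("transform", "one-minus-f")
                tree, support = bootstrap_support(matrix, n_boot, config.seed,
                                                  transform=transform)
                outgroup = config.tree.get("outgroup")
                if outgroup:
                    from .trees import root_with_outgroup

                    members = [s for s in matrix.sample_ids
                               if s == outgroup
                               or matrix.species_map.get(s) == outgroup]
                    tree = root_with_outgroup(tree, members or [outgroup])
                write_tree(tree, outdir / "nj_tree.nwk", support.entries,
                           min_displayed_support=50.0)
                write_support_table(support, outdir / "nj_support.tsv")
                manifest.add(outdir / "nj_tree.nwk", stage, {"bootstrap": n_boot})
                manifest.add(outdir / "nj_support.tsv", stage, {"bootstrap": n_boot})
                report["stages"][stage] = {
                    "n_bipartitions": len(support.entries),
                    "mean_support": (sum(support.entries.values())
                                     / max(len(support.entries), 1)),
                }
            elif stage == "hybridtest":
                matrix = _need_matrix(matrix, config.hybridtest)
                n_boot = int(config.hybridtest.get("boot", 100))
                rule = OutlierRule(
                    fence=config.hybridtest.get("fence", "tukey"),
                    min_delta=float(config.hybridtest.get("min_delta", 10.0)),
                )
                result = run_homoplasy_excess(matrix, n_boot, config.seed, rule)
                payload = {
                    "verdict_per_species": result.verdict_per_species,
                    "outliers": [
                        {"species": sp, "bipartition": sorted(bp.side),
                         "delta": d, "fence": f}
                        for sp, bp, d, f in result.outliers
                    ],
                }
                write_json(payload, outdir / "hybridtest.json")
                _write_delta_table(result, outdir / "hybridtest_deltas.tsv")
                manifest.add(outdir / "hybridtest.json", stage, {"boot": n_boot})
                manifest.add(outdir / "hybridtest_deltas.tsv", stage, {"boot": n_boot})
                report["stages"][stage] = {"flagged": result.flagged_species()}
            elif stage == "topotest":
                matrix = _need_matrix(matrix, config.topotest)
                topo_paths = config.topotest.get("topologies", {})
                if len(topo_paths) < 2:
                    raise AflPhyloError("topotest needs >= 2 topologies")
                topologies = {name: from_newick(Path(p).read_text())
                              for name, p in topo_paths.items()}
                conditioning = config.topotest.get("conditioning", "noabsencesites")
                model = estimate_state_frequencies(matrix, conditioning)
                sh = sh_test(matrix, topologies, model,
                             n_rell=int(config.topotest.get("rell", 1000)),
                             seed=config.seed)
                settings = McmcSettings(
                    n_generations=int(config.topotest.get("mcmc_gens", 20000)),
                    burnin_frac=float(config.topotest.get("burnin_frac", 0.5)),
                )
                marg = {name: marginal_likelihood_harmonic(t, model, matrix,
                                                           settings, config.seed)
                        for name, t in topologies.items()}
                bf = {}
                names = list(topologies)
                for i, a in enumerate(names):
                    for b in names[i + 1:]:
                        val, verdict = bayes_factor(marg[a].estimate, marg[b].estimate)
                        bf[f"{a}|{b}"] = {"2lnBF": val, "verdict": verdict}
                payload = {
                    "sh_pvalues": sh.sh_pvalues,
                    "lnl_deltas": sh.deltas,
                    "harmonic_mean_lnl": {n: m.per_run for n, m in marg.items()},
                    "bayes_factors": bf,
                }
                write_json(payload, outdir / "topotest.json")
                manifest.add(outdir / "topotest.json", stage, {})
                report["stages"][stage] = payload
        except Exception as exc:
            manifest.write()
            raise AflPhyloError(f"stage {stage!r} failed: {exc}") from exc
        log.info("stage %s: done in %.1fs", stage, time.time() - t0)
    manifest.write()
    write_json(report, outdir / "report.json")
    return report


def _call(peaks, thresholds):
    from .scoring import call_phenotypes

    return call_phenotypes(peaks, thresholds)


def _need_matrix(matrix, block: dict):
    if matrix is not None:
        return matrix
    path = block.get("matrix")
    if not path:
        raise AflPhyloError("no matrix available: provide 'matrix' path or enable "
                            "an upstream stage")
    return read_binary_matrix(path, block.get("dialect", "tsv"))


def _write_delta_table(result, path: Path) -> None:
    import pandas as pd

    bips = sorted({bp for rec in result.records for bp in rec.deltas},
                  key=lambda bp: sorted(bp.side))
    rows = []
    for rec in result.records:
        row = {"removed_species": rec.removed_species}
        for bp in bips:
            row["|".join(sorted(bp.side))] = rec.deltas.get(bp, float("nan"))
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
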