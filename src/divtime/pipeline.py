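"""Configuration-driven orchestration of the full dating analysis.

A scenario bundles the alignment, partitioning, calibrations, the root-age
prior scenario (narrow / wide / uncalibrated vicariance windows), the clock
model (or stepping-stone selection among the three), the MCMC budget, and
a seed.  ``run_scenario`` executes, in order: optional clock-model
selection, an empirical-Bayes clock-rate prior from a strict-clock
relative-height run, a prior-only (data-free) run exposing the realized
calibration priors, independent posterior runs pooled into a consensus
chronogram, and optional per-gene dating runs feeding the gene evaluation.
Everything is reproducible from the config plus seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .alignment import MultiGeneAlignment, PartitionScheme, build_partition_scheme
from .calibrations import Calibration, CalibrationSet
from .configio import load_calibrations
from .gene_eval import compare_gene, kendall_tau, mean_ci_widths
from .mcmc import (
    LognormalPrior,
    McmcConfig,
    Trace,
    asdsf,
    effective_sample_size,
    empirical_bayes_clock_prior,
    run_mcmc,
)
from .model_selection import SteppingStoneConfig, bayes_factor_2ln, stepping_stone_logml
from .posterior import PhyloDatingModel
from .summaries import concat_runs, majority_consensus, write_chronogram
from .trees import TimeTree

__all__ = ["ScenarioConfig", "validate_config", "run_scenario", "ROOT_SCENARIOS"]

logger = logging.getLogger("divtime")

#: the three root-age prior scenarios (My windows)
ROOT_SCENARIOS = {
    "narrow": (82.0, 85.0),
    "wide": (52.0, 85.0),
    "uncalibrated": (20.0, 4000.0),
}


@dataclass
class ScenarioConfig:
    alignment: MultiGeneAlignment | str | Path
    coding_genes: list[str] = field(default_factory=list)
    calibrations: CalibrationSet | str | Path | None = None
    root_scenario: str = "wide"
    clock: str = "IGR"  # strict | TK02 | IGR | select
    n_generations: int = 4000
    sample_every: int = 10
    n_runs: int = 2
    n_chains: int = 1
    temperature: float = 0.1
    burn_in: float = 0.25
    topology_moves: bool = True
    topology: TimeTree | None = None
    gene_eval: bool = False
    gene_generations: int | None = None
    height_generations: int = 1500
    ss_steps: int = 8
    ss_samples: int = 150
    outdir: str | Path | None = None
    seed: int = 1

    def budget(self, prior_only: bool = False) -> McmcConfig:
        return McmcConfig(
            n_generations=self.n_generations,
            sample_every=self.sample_every,
            n_chains=self.n_chains,
            temperature=self.temperature,
            n_runs=self.n_runs,
            burn_in=self.burn_in,
            prior_only=prior_only,
            topology_moves=self.topology_moves,
        )


def validate_config(config: ScenarioConfig) -> ScenarioConfig:
    """Resolve paths, check cross-references, normalise, and echo defaults.

    Raises ValueError with a list of problems when the config is unusable.
    """
    cfg = dataclasses.replace(config)
    errors: list[str] = []
    if isinstance(cfg.alignment, (str, Path)):
        path = Path(cfg.alignment)
        if not path.exists():
            errors.append(f"alignment file not found: {path}")
        else:
            cfg.alignment = MultiGeneAlignment.from_nexus(path)
    if isinstance(cfg.calibrations, (str, Path)):
        path = Path(cfg.calibrations)
        if not path.exists():
            errors.append(f"calibration file not found: {path}")
        else:
            cfg.calibrations = load_calibrations(path)
    if cfg.root_scenario not in ROOT_SCENARIOS:
        errors.append(f"unknown root scenario {cfg.root_scenario!r}")
    if cfg.clock not in ("strict", "TK02", "IGR", "select"):
        errors.append(f"unknown clock model {cfg.clock!r}")
    if cfg.n_generations <= 0:
        errors.append("MCMC budget must be positive")
    if not errors and cfg.calibrations is not None:
        taxa = set(cfg.alignment.taxa)
        for clade in cfg.calibrations.constraints:
            unknown = set(clade) - taxa
            if unknown:
                errors.append(f"constraint taxon not in alignment: {sorted(unknown)}")
        root = cfg.calibrations.root
        if root.max_age < root.min_age:
            warnings.warn("root window reversed; normalising", stacklevel=2)
            cfg.calibrations = dataclasses.replace(
                cfg.calibrations,
                root=Calibration.uniform(root.max_age, root.min_age, clade=root.clade),
            )
    if not errors and cfg.alignment is not None:
        unknown_coding = set(cfg.coding_genes) - set(cfg.alignment.gene_names)
        if unknown_coding:
            errors.append(f"coding gene not in alignment: {sorted(unknown_coding)}")
    if errors:
        raise ValueError("invalid scenario config: " + "; ".join(errors))
    logger.info("validated config: %s", _config_echo(cfg))
    return cfg


def _config_echo(cfg: ScenarioConfig) -> str:
    skip = {"alignment", "calibrations", "topology"}
    return json.dumps(
        {
            k: v
            for k, v in dataclasses.asdict(cfg).items()
            if k not in skip and isinstance(v, (int, float, str, bool, list))
        },
        sort_keys=True,
        default=str,
    )


def _scheme_for(cfg: ScenarioConfig) -> PartitionScheme:
    aln = cfg.alignment
    coding = [g in cfg.coding_genes for g in aln.gene_names]
    return build_partition_scheme(aln.gene_names, aln.gene_lengths, coding)


def _apply_scenario(cals: CalibrationSet, scenario: str) -> CalibrationSet:
    lo, hi = ROOT_SCENARIOS[scenario]
    return dataclasses.replace(
        cals, root=Calibration.uniform(lo, hi, clade=cals.root.clade)
    )


def estimate_tree_height_subs(
    aln: MultiGeneAlignment,
    scheme: PartitionScheme,
    cals: CalibrationSet,
    seed: int,
    n_generations: int = 1500,
    topology: TimeTree | None = None,
) -> float:
    """Posterior median tree height in substitutions/site from a
    strict-clock run on relative time (root age pinned to one)."""
    # relative time: root pinned at 1, fossil calibrations dropped (their
    # minima live on the absolute scale) but their monophyly kept
    rel = CalibrationSet(
        root=Calibration.uniform(1.0, 1.0, clade=cals.root.clade),
        nodes=[],
        extra_constraints=list(cals.constraints),
    )
    model = PhyloDatingModel(
        aln,
        scheme,
        rel,
        clock_kind="strict",
        clock_rate_prior=LognormalPrior(median=0.1, sdlog=2.0),
        topology=topology,
        topology_moves=topology is None,
    )
    cfg = McmcConfig(n_generations=n_generations, sample_every=5, n_chains=1)
    trace = run_mcmc(model, cfg, np.random.default_rng([seed, 977]))
    kept = trace.discard_burn_in(0.5)
    height = float(kept.params["tree_height_subs"].median())
    if height <= 0:
        raise ValueError("degenerate tree height estimate")
    return height


def select_clock_model(
    aln: MultiGeneAlignment,
    scheme: PartitionScheme,
    cals: CalibrationSet,
    clock_rate_prior: LognormalPrior,
    cfg: ScenarioConfig,
) -> tuple[str, dict[str, float]]:
    """Stepping-stone comparison of strict / TK02 / IGR; returns the winner
    and the log marginal likelihoods."""
    logml = {}
    for kind in ("strict", "TK02", "IGR"):
        model = PhyloDatingModel(
            aln,
            scheme,
            cals,
            clock_kind=kind,
            clock_rate_prior=clock_rate_prior,
            topology=cfg.topology,
            topology_moves=False,
        )
        ss = SteppingStoneConfig(
            n_steps=cfg.ss_steps,
            burn_in_generations=max(cfg.ss_samples // 2, 50),
            samples_per_step=cfg.ss_samples,
            sample_every=2,
        )
        value, _ = stepping_stone_logml(model, ss, np.random.default_rng([cfg.seed, hash(kind) % 2**16]))
        logml[kind] = value
        logger.info("stepping-stone logml(%s) = %.3f", kind, value)
    best = max(logml, key=logml.get)
    return best, logml


def run_scenario(config: ScenarioConfig) -> dict:
    """Execute the full analysis for one scenario; returns a report dict.

    Stages: (1) optional clock selection, (2) prior-only run, (3) posterior
    runs pooled into a consensus chronogram, (4) per-gene runs and
    congruence/precision statistics (when ``gene_eval``).  Partial outputs
    are written as stages finish when ``outdir`` is set.
    """
    cfg = validate_config(config)
    aln: MultiGeneAlignment = cfg.alignment
    scheme = _scheme_for(cfg)
    cals = _apply_scenario(cfg.calibrations, cfg.root_scenario)
    outdir = Path(cfg.outdir) if cfg.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)

    report: dict = {
        "config": json.loads(_config_echo(cfg)),
        "scenario": cfg.root_scenario,
        "root_window": ROOT_SCENARIOS[cfg.root_scenario],
        "n_taxa": aln.n_taxa,
        "n_sites": aln.n_sites,
        "n_partitions": len(scheme),
    }

    def stage(name):
        logger.info("stage: %s", name)

    try:
        stage("clock-rate prior")
        height = estimate_tree_height_subs(
            aln, scheme, cals, cfg.seed, n_generations=cfg.height_generations,
            topology=cfg.topology,
        )
        rate_prior = empirical_bayes_clock_prior(height, cals.root)
        report["tree_height_subs_strict"] = height
        report["clock_rate_prior_median"] = rate_prior.median

        clock = cfg.clock
        if clock == "select":
            stage("clock model selection")
            clock, logml = select_clock_model(aln, scheme, cals, rate_prior, cfg)
            report["clock_logml"] = logml
            report["clock_2lnBF_best_vs_others"] = {
                k: bayes_factor_2ln(logml[clock], v) for k, v in logml.items() if k != clock
            }
        report["clock"] = clock

        model = PhyloDatingModel(
            aln,
            scheme,
            cals,
            clock_kind=clock,
            clock_rate_prior=rate_prior,
            topology=cfg.topology,
            topology_moves=cfg.topology_moves and cfg.topology is None,
        )

        stage("prior-only run (realized priors)")
        prior_trace = run_mcmc(
            model, cfg.budget(prior_only=True), np.random.default_rng([cfg.seed, 1])
        )
        kept = prior_trace.discard_burn_in(cfg.burn_in)
        report["realized_prior"] = {
            "root_age_median": float(kept.params["root_age"].median()),
            "root_age_ci": _ci(kept.params["root_age"]),
            "calibrated_ages_median": {
                c: float(kept.params[c].median())
                for c in kept.params.columns
                if c.startswith("cal_age_")
            },
        }

        stage("posterior runs")
        traces: list[Trace] = []
        for run in range(cfg.n_runs):
            trace = run_mcmc(
                model, cfg.budget(), np.random.default_rng([cfg.seed, 100 + run]), run_id=run
            )
            traces.append(trace)
            if outdir:
                trace.write(outdir / f"run{run}")
        pooled = concat_runs(traces, cfg.burn_in)
        report["ess_log_likelihood"] = effective_sample_size(
            pooled.params["log_likelihood"].to_numpy()
        )
        if len(traces) >= 2 and traces[0].trees and cfg.topology_moves and cfg.topology is None:
            report["asdsf"] = asdsf([t.discard_burn_in(cfg.burn_in) for t in traces])
            report["asdsf_converged"] = report["asdsf"] <= 0.01

        stage("summaries")
        consensus = majority_consensus(pooled.trees)
        table = consensus.node_table()
        root_ages = pooled.params["root_age"]
        report["posterior"] = {
            "root_age_median": float(root_ages.median()),
            "root_age_mean": float(root_ages.mean()),
            "root_age_ci": _ci(root_ages),
            "mean_ci_width": float(table["ci_width"].mean()),
            "n_consensus_clades": int(len(table)),
            "tree_height_subs_median": float(pooled.params["tree_height_subs"].median()),
        }
        if outdir:
            write_chronogram(consensus, outdir / "chronogram.nex")
            table.to_csv(outdir / "node_table.tsv", sep="\t", index=False)

        if cfg.gene_eval:
            stage("per-gene runs")
            report["genes"] = _gene_stage(cfg, cals, consensus, pooled, outdir)
    except Exception as exc:  # annotate failures with the active stage
        raise RuntimeError(f"scenario failed: {exc}") from exc

    if outdir:
        path = outdir / "report.json"
        payload = json.dumps(report, indent=2, sort_keys=True, default=_jsonable)
        path.write_text(payload)
        report["report_sha256"] = hashlib.sha256(payload.encode()).hexdigest()
    return report


def _gene_stage(cfg, cals, consensus, pooled, outdir):
    from .summaries import summarize_node_ages

    aln: MultiGeneAlignment = cfg.alignment
    combined = {s.split: s for s in consensus.summaries.values()}
    gene_gens = cfg.gene_generations or cfg.n_generations
    out = {}
    per_gene_summaries = {}
    for gi, gene in enumerate(aln.gene_names):
        sub = aln.subset_genes([gene])
        coding = [gene in cfg.coding_genes]
        scheme = build_partition_scheme([gene], [sub.gene_lengths[0]], coding)
        height = estimate_tree_height_subs(
            sub, scheme, cals, cfg.seed + 7 * gi, n_generations=800, topology=cfg.topology
        )
        model = PhyloDatingModel(
            sub,
            scheme,
            cals,
            clock_kind=cfg.clock if cfg.clock != "select" else "IGR",
            clock_rate_prior=empirical_bayes_clock_prior(height, cals.root),
            topology=cfg.topology,
            topology_moves=cfg.topology_moves and cfg.topology is None,
        )
        gcfg = McmcConfig(
            n_generations=gene_gens,
            sample_every=cfg.sample_every,
            n_chains=cfg.n_chains,
            temperature=cfg.temperature,
            topology_moves=cfg.topology_moves,
        )
        trace = run_mcmc(model, gcfg, np.random.default_rng([cfg.seed, 500 + gi]))
        kept = trace.discard_burn_in(cfg.burn_in)
        summaries = summarize_node_ages(kept, min_pp=0.5)
        per_gene_summaries[gene] = summaries
        comp = compare_gene(gene, summaries, combined)
        entry = {
            "n_matched": len(comp.matched),
            "n_missing": len(comp.missing),
        }
        if len(comp.matched) >= 2:
            g, c = comp.medians()
            tau, p = kendall_tau(g, c)
            entry["kendall_tau"] = tau
            entry["kendall_p"] = p
        widths = [summaries[s].width for s in comp.matched]
        if widths:
            entry["mean_ci_width"] = float(np.mean(widths))
            entry["widths"] = [float(w) for w in widths]
        out[gene] = entry
        if outdir:
            comp.table().to_csv(outdir / f"gene_{gene}.tsv", sep="\t", index=False)
    out["_mean_ci_widths"] = {
        k: float(v) for k, v in mean_ci_widths(per_gene_summaries).items()
    }
    return out


def _ci(series: pd.Series) -> list[float]:
    lo, hi = np.percentile(series.to_numpy(), [2.5, 97.5])
    return [float(lo), float(hi)]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (tuple, set, frozenset)):
        return list(obj)
    return str(obj)
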