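"""End-to-end orchestration: simulate/load → screen → quantify → test → report.

One entry point, :func:`run_pipeline`, executes every stage in order, writes
per-stage TSV outputs plus a machine-readable ``report.json``, and records in
``run_log.yaml`` every parameter needed to reproduce the run (the full
configuration, the derived per-stage seeds, and the package version). Figure
data are exported as tables: per-line abundance box data, per-line genus
stacked-bar data (5% threshold) and the between-arm genus shift table (1%
threshold).
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .abundance import (
    fold_change_summary,
    log_abundance_model,
    per_group_kruskal,
    significance_stars,
)
from .composition import (
    alpha_compare,
    choose_rarefaction_depth,
    genus_aggregate,
    genus_shift_table,
    per_line_beta_report,
    rarefy,
)
from .containers import ExperimentBundle
from .decontam import decontaminate
from .io import read_bundle_dir, write_bundle
from .quantify import estimates_frame, quantify_all
from .simulate import SimulationConfig, simulate_experiment

log = logging.getLogger("ampliquant")


@dataclass
class PipelineConfig:
    """Thresholds, seeds and paths for one pipeline run."""

    out_dir: str = "ampliquant_run"
    bundle_dir: str | None = None          # read input here; simulate if None
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    decontam_threshold: float = 1.0
    decontam_scope: str = "global"
    alpha: float = 0.05
    rarefaction_fraction: float = 0.8
    permutations: int = 999
    abundance_model: str = "two_way_fixed"
    genus_plot_threshold: float = 0.05     # stacked-bar composition data
    genus_shift_threshold: float = 0.01    # between-arm shift table
    seed: int = 0

    def config_hash(self) -> str:
        blob = json.dumps(_as_plain(asdict(self)), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _as_plain(obj):
    if isinstance(obj, dict):
        return {k: _as_plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_as_plain(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


class StageError(RuntimeError):
    """A pipeline stage failed; earlier partial outputs are retained."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _tests_frame(results, skipped) -> pd.DataFrame:
    rows = [{
        "group": r.grouping, "test": r.test_name,
        "n_control": r.n_per_group.get("control", 0),
        "n_hotshot": r.n_per_group.get("hotshot", 0),
        "statistic": r.statistic, "p": r.p_value,
        "direction": r.effect_direction, "stars": r.stars, "note": r.note,
    } for r in results]
    rows += [{"group": g, "test": "", "n_control": 0, "n_hotshot": 0,
              "statistic": np.nan, "p": np.nan, "direction": 0, "stars": "",
              "note": f"skipped: {reason}"} for g, reason in skipped]
    return pd.DataFrame(rows)


def run_pipeline(config: PipelineConfig, bundle: ExperimentBundle | None = None,
                 write: bool = True) -> dict:
    """Execute all stages; returns the report dict (also written as JSON).

    A failing stage raises :class:`StageError` naming the stage; outputs of
    completed stages remain on disk.
    """
    out = Path(config.out_dir)
    if write:
        out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(config.seed)
    seeds = {name: int(np.random.default_rng(child).integers(2 ** 31))
             for name, child in zip(
                 ["simulation", "alpha_rarefaction", "beta"], ss.spawn(3))}
    report: dict = {"config_hash": config.config_hash(),
                    "pipeline_version": __version__, "seeds": seeds}

    # -- stage: input -------------------------------------------------------
    stage = "input"
    try:
        if bundle is None:
            if config.bundle_dir:
                bundle = read_bundle_dir(config.bundle_dir)
                log.info("read bundle from %s", config.bundle_dir)
            else:
                sim = SimulationConfig(**{**asdict(config.simulation),
                                          "seed": seeds["simulation"]})
                bundle, _truth = simulate_experiment(sim)
                report["simulated"] = True
                if write:
                    write_bundle(bundle, out / "bundle")
        report["n_samples"] = len(bundle.counts.sample_ids)
        report["n_genotypes"] = len(bundle.counts.genotype_ids)
    except StageError:
        raise
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: decontamination --------------------------------------------
    stage = "decontamination"
    try:
        dec = decontaminate(bundle, threshold=config.decontam_threshold,
                            scope=config.decontam_scope)
        report["decontamination"] = {
            "class_counts": dec.ledger.class_counts(),
            "threshold": config.decontam_threshold,
            "scope": config.decontam_scope,
            "n_kept_samples": len(dec.kept_samples),
            "exclusions": dec.exclusions,
        }
        if write:
            dec.ledger.to_tsv(out / "decontam_ledger.tsv")
            cleaned = dec.decontaminated.counts.copy()
            cleaned.index.name = "genotype_id"
            cleaned.to_csv(out / "decontaminated_counts.tsv", sep="\t")
            dec.spike_reads.rename_axis("sample_id").to_csv(
                out / "spike_reads.tsv", sep="\t")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: quantification ---------------------------------------------
    stage = "quantification"
    try:
        estimates, refused = quantify_all(
            bundle, dec.decontaminated, dec.spike_reads,
            sample_ids=dec.kept_samples)
        est = estimates_frame(estimates)
        report["quantification"] = {
            "n_quantified": len(estimates),
            "unquantifiable": refused,
            "ratio_range": [float(est["ratio"].min()), float(est["ratio"].max())]
            if len(est) else None,
            "copies_range": [float(est["copies_per_insect"].min()),
                             float(est["copies_per_insect"].max())]
            if len(est) else None,
        }
        if write:
            est.rename_axis("sample_id").to_csv(
                out / "abundance_estimates.tsv", sep="\t")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: abundance statistics ---------------------------------------
    stage = "abundance_statistics"
    try:
        fit = log_abundance_model(estimates, bundle.metadata,
                                  model=config.abundance_model)
        kw_line, kw_line_skip = per_group_kruskal(estimates, bundle.metadata,
                                                  group_by="line")
        kw_size, kw_size_skip = per_group_kruskal(estimates, bundle.metadata,
                                                  group_by="size_class")
        per_line_folds, fold_summary = fold_change_summary(
            estimates, bundle.metadata, model_fit=fit)
        sig_lines = [r.grouping for r in kw_line
                     if r.p_value < config.alpha and r.effect_direction > 0]
        report["abundance"] = {
            "model": fit.summary_row(),
            "n_lines_tested": len(kw_line),
            "n_lines_significant_lower": len(sig_lines),
            "significant_lines": sig_lines,
            "size_classes_significant": [
                r.grouping for r in kw_size if r.p_value < config.alpha],
            "fold_summary": _as_plain(fold_summary),
        }
        if write:
            tests = pd.concat([_tests_frame(kw_line, kw_line_skip),
                               _tests_frame(kw_size, kw_size_skip)])
            tests.to_csv(out / "abundance_tests.tsv", sep="\t", index=False)
            per_line_folds.to_csv(out / "fold_changes.tsv", sep="\t",
                                  index=False)
            # Fig-2-style box data: per-sample log10 copies with line/arm
            meta = bundle.metadata_by_id
            box = est[["copies_per_insect"]].copy()
            box["log10_copies"] = np.log10(box["copies_per_insect"])
            box["line"] = [meta[s].line for s in box.index]
            box["treatment"] = [meta[s].treatment for s in box.index]
            box.rename_axis("sample_id").to_csv(
                out / "figdata_abundance_box.tsv", sep="\t")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: diversity ---------------------------------------------------
    stage = "diversity"
    try:
        meta = bundle.metadata_by_id
        lines = sorted({meta[s].line for s in dec.kept_samples})
        alpha_ss = np.random.SeedSequence(seeds["alpha_rarefaction"])
        rare_tables = []
        rarefaction_depths = {}
        for line, child in zip(lines, alpha_ss.spawn(len(lines))):
            sub = dec.decontaminated.subset_samples(
                [s for s in dec.kept_samples if meta[s].line == line])
            if sub.shape[1] < 2:
                continue
            plan = choose_rarefaction_depth(sub, config.rarefaction_fraction)
            rarefaction_depths[line] = plan.depth
            rare = rarefy(sub, plan.depth, child)
            if rare.shape[1]:
                rare_tables.append(rare.counts)
        alpha_results, alpha_skipped = ([], [])
        if rare_tables:
            # per-line rarefied tables share the genotype index; comparisons
            # are within line, so depths may differ between lines
            from .containers import GenotypeCountTable
            combined = GenotypeCountTable(pd.concat(rare_tables, axis=1),
                                          level=dec.decontaminated.level)
            alpha_results, alpha_skipped = alpha_compare(
                combined, bundle.metadata)
        beta_results, beta_skipped = per_line_beta_report(
            dec.decontaminated, bundle.metadata, sample_ids=dec.kept_samples,
            permutations=config.permutations, seed=seeds["beta"],
            min_sample_fraction=config.rarefaction_fraction)
        report["diversity"] = {
            "rarefaction_depths": rarefaction_depths,
            "alpha_significant_lines": [
                r.grouping for r in alpha_results if r.p_value < config.alpha],
            "beta_significant_lines": [
                r.line for r in beta_results
                if r.permanova.p_value < config.alpha],
            "permdisp_significant_lines": [
                r.line for r in beta_results
                if r.permdisp.p_value < config.alpha],
            "n_lines_beta_tested": len(beta_results),
            "beta_skipped": beta_skipped,
            "pcoa_axis1_percent": {
                r.line: float(100 * r.ordination.proportion_explained[0])
                for r in beta_results if len(r.ordination.proportion_explained)},
        }
        if write:
            rows = []
            alpha_by_line = {r.grouping: r for r in alpha_results}
            for r in beta_results:
                a = alpha_by_line.get(r.line)
                rows.append({
                    "line": r.line, "n_control": r.n_control,
                    "n_hotshot": r.n_hotshot,
                    "rarefaction_depth": r.rarefaction_depth,
                    "shannon_H": a.statistic if a else np.nan,
                    "shannon_p": a.p_value if a else np.nan,
                    "shannon_stars": a.stars if a else "",
                    "permanova_F": r.permanova.statistic,
                    "permanova_p": r.permanova.p_value,
                    "permanova_stars": r.permanova.stars,
                    "permdisp_F": r.permdisp.statistic,
                    "permdisp_p": r.permdisp.p_value,
                    "pcoa_axis1_percent":
                        float(100 * r.ordination.proportion_explained[0])
                        if len(r.ordination.proportion_explained) else np.nan,
                })
            pd.DataFrame(rows).to_csv(out / "shannon_braycurtis.tsv",
                                      sep="\t", index=False)
    except Exception as exc:
        raise StageError(stage, exc) from exc

    # -- stage: genus summaries ---------------------------------------------
    stage = "genus_summaries"
    try:
        stacked = []
        for line in lines:
            sub = dec.decontaminated.subset_samples(
                [s for s in dec.kept_samples if meta[s].line == line])
            if not sub.shape[1]:
                continue
            rel = genus_aggregate(sub, bundle.taxonomy,
                                  config.genus_plot_threshold)
            longf = rel.rename_axis("genus").reset_index().melt(
                id_vars="genus", var_name="sample_id", value_name="relabund")
            longf.insert(0, "line", line)
            stacked.append(longf)
        ctrl = [s for s in dec.kept_samples if meta[s].treatment == "control"]
        trt = [s for s in dec.kept_samples if meta[s].treatment == "hotshot"]
        shift = None
        if ctrl and trt:
            rel_c = genus_aggregate(dec.decontaminated.subset_samples(ctrl),
                                    bundle.taxonomy, config.genus_shift_threshold)
            rel_t = genus_aggregate(dec.decontaminated.subset_samples(trt),
                                    bundle.taxonomy, config.genus_shift_threshold)
            shift = genus_shift_table(rel_c, rel_t)
            report["genus_shift_max_abs"] = float(shift["shift"].abs().max())
        if write:
            if stacked:
                pd.concat(stacked).to_csv(out / "figdata_genus_stackedbar.tsv",
                                          sep="\t", index=False)
            if shift is not None:
                shift.rename_axis("genus").to_csv(
                    out / "figdata_genus_shift.tsv", sep="\t")
    except Exception as exc:
        raise StageError(stage, exc) from exc

    if write:
        with open(out / "report.json", "w") as fh:
            json.dump(_as_plain(report), fh, indent=2)
        with open(out / "run_log.yaml", "w") as fh:
            yaml.safe_dump({
                "pipeline_version": __version__,
                "config": _as_plain(asdict(config)),
                "config_hash": config.config_hash(),
                "derived_seeds": seeds,
            }, fh, sort_keys=False)
    return report
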