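"""Blank-based contaminant screening for amplicon count tables.

Every genotype is assigned exactly one class:

* ``spikein`` — the quantification plasmid, split out before anything else;
* ``nontarget`` — chloroplast / mitochondrial / archaeal / chimeric reads,
  identified from taxonomy flags;
* ``contaminant`` — reagent or cross-contamination, judged by comparing the
  genotype's relative abundance in negative-control libraries (blanks) against
  experimental libraries;
* ``symbiont`` — everything else: putative insect-associated microbes.

The contaminant rule: compute each genotype's relative abundance per sample
(count over the sample's bacterial library size, i.e. after spike-in and
non-target removal so that the deliberately spike-dominated blanks cannot
distort denominators). The evidence statistic is the maximum over blanks
versus the maximum over experimental samples; a genotype at least
``threshold`` times as prominent in its best blank as in its best experimental
library is called a contaminant. Blank-only genotypes (ratio = infinity) are
always contaminants. Every call is recorded in an auditable ledger with the
two maxima, their ratio, and the rule that fired.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .containers import (
    BLANK_ROLES,
    ExperimentBundle,
    GenotypeCountTable,
)

CLASSES = ("symbiont", "contaminant", "nontarget", "spikein")

_LEDGER_COLS = ["class", "max_blank_relabund", "max_experimental_relabund",
                "blank_to_sample_ratio", "rule_fired"]


class DecontamLedger:
    """Per-genotype classification with the evidence behind each call."""

    def __init__(self, frame: pd.DataFrame | None = None):
        if frame is None:
            frame = pd.DataFrame(columns=_LEDGER_COLS)
        self.frame = frame[_LEDGER_COLS].copy()
        bad = set(self.frame["class"]) - set(CLASSES)
        if bad:
            raise ValueError(f"unknown ledger classes: {sorted(bad)}")

    @classmethod
    def from_records(cls, records: dict) -> "DecontamLedger":
        frame = pd.DataFrame.from_dict(records, orient="index")
        if frame.empty:
            return cls()
        return cls(frame)

    def merge(self, other: "DecontamLedger") -> "DecontamLedger":
        overlap = self.frame.index.intersection(other.frame.index)
        if len(overlap):
            raise ValueError(
                f"genotypes classified twice: {list(overlap[:5])}"
            )
        return DecontamLedger(pd.concat([self.frame, other.frame]))

    def genotypes_in_class(self, cls_name: str) -> list:
        return list(self.frame.index[self.frame["class"] == cls_name])

    @property
    def symbionts(self) -> list:
        return self.genotypes_in_class("symbiont")

    @property
    def contaminants(self) -> list:
        return self.genotypes_in_class("contaminant")

    def class_of(self, genotype_id) -> str:
        return self.frame.at[genotype_id, "class"]

    def class_counts(self) -> dict[str, int]:
        vc = self.frame["class"].value_counts()
        return {c: int(vc.get(c, 0)) for c in CLASSES}

    def to_tsv(self, path) -> None:
        out = self.frame.copy()
        out.index.name = "genotype_id"
        out.to_csv(path, sep="\t")

    def __len__(self) -> int:
        return len(self.frame)


def strip_nontarget(bundle: ExperimentBundle) -> tuple[ExperimentBundle, DecontamLedger]:
    """Remove genotypes flagged chloroplast/mitochondria/archaea/chimera.

    Returns the reduced bundle and a partial ledger recording each removed
    genotype as ``nontarget`` (rule = the flag that fired). Counts of all
    other genotypes are unchanged.
    """
    flagged = bundle.taxonomy.flagged()
    records = {}
    for gid in flagged:
        if gid in bundle.spike_genotype_ids:
            continue  # spike identity takes precedence; handled by split_spikein
        records[gid] = {
            "class": "nontarget",
            "max_blank_relabund": np.nan,
            "max_experimental_relabund": np.nan,
            "blank_to_sample_ratio": np.nan,
            "rule_fired": "flag:" + ",".join(sorted(bundle.taxonomy.flags_of(gid))),
        }
    keep = [g for g in bundle.counts.genotype_ids if g not in records]
    return bundle.with_counts(bundle.counts.subset_genotypes(keep)), \
        DecontamLedger.from_records(records)


def split_spikein(
    bundle: ExperimentBundle,
) -> tuple[GenotypeCountTable, pd.Series, DecontamLedger]:
    """Split spike-in genotype rows from the bacterial table.

    Returns the bacterial table (spike rows removed), per-sample spike read
    counts (summed over all spike sequence variants), and a partial ledger
    recording spike genotypes. Spike ids absent from the table are recorded
    with all-zero reads and a warning; bacterial + spike reads partition the
    original column totals.
    """
    if not bundle.spike_genotype_ids:
        raise ValueError("bundle has no spike genotype ids")
    present = [g for g in bundle.spike_genotype_ids
               if g in set(bundle.counts.genotype_ids)]
    absent = sorted(set(bundle.spike_genotype_ids) - set(present))
    if absent:
        warnings.warn(
            f"spike genotypes absent from count table (recorded as zero reads): "
            f"{absent}", stacklevel=2)
    spike_reads = (
        bundle.counts.counts.loc[present].sum(axis=0)
        if present else pd.Series(0, index=bundle.counts.sample_ids)
    ).astype(np.int64)
    spike_reads.name = "spike_reads"
    keep = [g for g in bundle.counts.genotype_ids if g not in set(present)]
    bacterial = bundle.counts.subset_genotypes(keep)
    records = {gid: {
        "class": "spikein", "max_blank_relabund": np.nan,
        "max_experimental_relabund": np.nan, "blank_to_sample_ratio": np.nan,
        "rule_fired": "spike_id",
    } for gid in bundle.spike_genotype_ids}
    return bacterial, spike_reads, DecontamLedger.from_records(records)


def _relabund_maxima(rel: pd.DataFrame, cols: list) -> pd.Series:
    """Row-wise max of relative abundance over the given samples (0 if none)."""
    if not cols:
        return pd.Series(0.0, index=rel.index)
    return rel[cols].max(axis=1).fillna(0.0)


def classify_contaminants(
    bacterial: GenotypeCountTable,
    bundle: ExperimentBundle,
    threshold: float = 1.0,
    scope: str = "global",
    aggregation: str = "max",
) -> DecontamLedger:
    """Classify each bacterial genotype as contaminant or symbiont.

    Parameters
    ----------
    bacterial : GenotypeCountTable
        Count table after spike-in and non-target removal; its column sums are
        the bacterial library sizes used as relative-abundance denominators.
    bundle : ExperimentBundle
        Supplies sample roles (which samples are blanks of which type).
    threshold : float
        Contaminant iff blank-to-sample ratio >= threshold. Default 1.0: a
        genotype at least as prominent in a blank as in its best sample is not
        credible as a symbiont.
    scope : {"global", "per_blank_type"}
        ``global`` pools all blanks; ``per_blank_type`` applies the rule per
        blank role and flags a genotype if any blank type fires.
    aggregation : {"max", "mean"}
        Statistic over each side's samples. Default ``max``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if scope not in ("global", "per_blank_type"):
        raise ValueError(f"unknown scope {scope!r}")
    if aggregation not in ("max", "mean"):
        raise ValueError(f"unknown aggregation {aggregation!r}")

    meta = bundle.metadata_by_id
    sizes = bacterial.library_sizes
    zero_blanks = [s for s in bacterial.sample_ids
                   if meta[s].is_blank and sizes[s] == 0]
    if zero_blanks:
        warnings.warn(
            f"blanks with zero bacterial reads ignored in maxima: {zero_blanks}",
            stacklevel=2)
    usable = [s for s in bacterial.sample_ids if sizes[s] > 0]
    blank_cols = [s for s in usable if meta[s].is_blank]
    exp_cols = [s for s in usable
                if not meta[s].is_blank and not meta[s].excluded]
    if not any(meta[s].is_blank for s in bacterial.sample_ids):
        raise ValueError("no blank samples: contaminant classification is "
                         "impossible")
    if not blank_cols:
        # blanks exist but carry no bacterial reads: no contamination evidence
        warnings.warn("all blanks have zero bacterial reads; no genotype can "
                      "be called contaminant", stacklevel=2)
    if not exp_cols:
        raise ValueError("no experimental samples with positive bacterial "
                         "library size")

    rel = bacterial.relative_abundance()
    agg = (lambda df, cols: df[cols].max(axis=1).fillna(0.0)) if aggregation == "max" \
        else (lambda df, cols: df[cols].mean(axis=1).fillna(0.0))
    max_exp = agg(rel, exp_cols)

    if scope == "global":
        blank_sets = {"blanks": blank_cols}
    else:
        blank_sets = {role: [s for s in blank_cols if meta[s].role == role]
                      for role in BLANK_ROLES}
    blank_sets = {k: v for k, v in blank_sets.items() if v}

    per_set_max = {name: agg(rel, cols) for name, cols in blank_sets.items()}
    max_blank = (pd.DataFrame(per_set_max).max(axis=1) if per_set_max
                 else pd.Series(0.0, index=rel.index))

    records = {}
    for gid in bacterial.genotype_ids:
        mb = float(max_blank[gid])
        me = float(max_exp[gid])
        fired = None
        for name, series in per_set_max.items():
            b = float(series[gid])
            if me > 0:
                ratio_s = b / me
            elif b > 0:
                ratio_s = np.inf
            else:
                ratio_s = 0.0
            if ratio_s >= threshold and (b > 0 or me > 0):
                fired = name
                break
        if me > 0:
            ratio = mb / me
        elif mb > 0:
            ratio = np.inf
        else:
            ratio = 0.0
        if mb == 0 and me == 0:
            cls, rule = "symbiont", "no_reads"
        elif fired is not None:
            cls = "contaminant"
            rule = (f"ratio>={threshold:g}[{fired}]" if scope == "per_blank_type"
                    else f"ratio>={threshold:g}")
            if np.isinf(ratio):
                rule = "blank_only"
        else:
            cls, rule = "symbiont", f"ratio<{threshold:g}"
        records[gid] = {
            "class": cls, "max_blank_relabund": mb,
            "max_experimental_relabund": me, "blank_to_sample_ratio": ratio,
            "rule_fired": rule,
        }
    return DecontamLedger.from_records(records)


def apply_ledger(table: GenotypeCountTable, ledger: DecontamLedger) -> GenotypeCountTable:
    """Retain only symbiont-class genotypes, counts unchanged."""
    missing = [g for g in table.genotype_ids if g not in ledger.frame.index]
    if missing:
        raise ValueError(f"genotypes missing from ledger: {missing[:5]}")
    keep = [g for g in table.genotype_ids if ledger.class_of(g) == "symbiont"]
    return table.subset_genotypes(keep)


def filter_samples(
    bundle: ExperimentBundle, decontaminated: GenotypeCountTable
) -> tuple[list, list[tuple[str, str]]]:
    """Select experimental samples usable for downstream statistics.

    Blanks are dropped (reason ``control``), samples flagged excluded in the
    metadata keep their recorded reason (e.g. incorrect indexes), and samples
    with no bacterial reads left after decontamination are dropped with reason
    ``zero abundance of bacteria``. Returns (kept ids, exclusion log).
    """
    sizes = decontaminated.library_sizes
    kept, exclusions = [], []
    for sid in decontaminated.sample_ids:
        m = bundle.metadata_by_id[sid]
        if m.is_blank:
            exclusions.append((sid, "control"))
        elif m.excluded:
            exclusions.append((sid, m.excluded_reason or "excluded in metadata"))
        elif sizes[sid] == 0:
            exclusions.append((sid, "zero abundance of bacteria"))
        else:
            kept.append(sid)
    if not kept:
        warnings.warn("no samples retained after filtering", stacklevel=2)
    return kept, exclusions


@dataclass
class DecontamResult:
    """Everything the screening stage produces, bundled for the pipeline."""

    bacterial: GenotypeCountTable          # after non-target + spike removal
    spike_reads: pd.Series                 # per sample
    ledger: DecontamLedger                 # full partition of all genotypes
    decontaminated: GenotypeCountTable     # symbiont-class genotypes only
    kept_samples: list = field(default_factory=list)
    exclusions: list = field(default_factory=list)


def decontaminate(
    bundle: ExperimentBundle,
    threshold: float = 1.0,
    scope: str = "global",
    aggregation: str = "max",
) -> DecontamResult:
    """Run the full screening stage: strip non-targets, split the spike-in,
    classify contaminants, apply the ledger, and filter samples."""
    stripped, ledger_nt = strip_nontarget(bundle)
    bacterial, spike_reads, ledger_sp = split_spikein(stripped)
    ledger_cls = classify_contaminants(bacterial, bundle, threshold=threshold,
                                       scope=scope, aggregation=aggregation)
    ledger = ledger_nt.merge(ledger_sp).merge(ledger_cls)
    clean = apply_ledger(bacterial, ledger)
    kept, exclusions = filter_samples(bundle, clean)
    return DecontamResult(bacterial=bacterial, spike_reads=spike_reads,
                          ledger=ledger, decontaminated=clean,
                          kept_samples=kept, exclusions=exclusions)
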