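"""Synthetic quantitative amplicon experiments with known ground truth.

The generator emulates the statistical structure the pipeline assumes for a
multi-species insect collection:

* per host line, a community profile with one dominant symbiont and a
  commensal tail; per specimen, composition jitters around the line profile
  (Dirichlet) and the true amplifiable 16S copy number is log-normal around
  the line mean, divided by the treatment fold in the treated arm;
* a spike-in plasmid at a fixed copy number added to a fixed fraction of
  each homogenate;
* a reagent contaminant pool at a constant template level per library —
  constant, not proportional to the insect's template, which is what makes
  contamination relatively more prominent exactly when biological template
  drops (treated or low-biomass specimens);
* negative controls: extraction blanks containing contaminant plus spike
  template, and PCR blanks containing contaminant template only;
* reads drawn multinomially from the template proportions at a log-normal,
  bounded sequencing depth.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .containers import (
    ExperimentBundle,
    GenotypeCountTable,
    SampleMetadata,
    TaxonomyTable,
)

SPIKE_ID = "Ec5001_spike"

_SYMBIONT_GENERA = [
    "Wolbachia", "Buchnera", "Lactobacillus", "Acetobacter", "Cardinium",
    "Blattabacterium", "Snodgrassella", "Gilliamella", "Spiroplasma",
    "Rickettsia", "Serratia", "Sodalis", "Arsenophonus", "Enterococcus",
    "Lactococcus", "Bartonella", "Frischella", "Commensalibacter",
    "Bifidobacterium", "Providencia", "Morganella", "Weissella",
]
_CONTAMINANT_GENERA = [
    "Ralstonia", "Sphingomonas", "Bradyrhizobium", "Methylobacterium",
    "Burkholderia", "Cutibacterium", "Staphylococcus", "Streptococcus",
    "Corynebacterium", "Acinetobacter", "Delftia", "Stenotrophomonas",
    "Pelomonas", "Herbaspirillum", "Comamonas", "Micrococcus", "Kocuria",
]


@dataclass
class SimulationConfig:
    """Study-design parameters of a synthetic experiment.

    Defaults mirror the emulated study's design: 19 host lines (three species
    contributing two culture lines each), roughly 8–12 specimens per
    treatment arm, sequencing depths spanning ~55–93,394 reads, 10,000 spike
    copies in 20% of the homogenate, a 15-fold treatment reduction of
    amplifiable template, and 6/7/3 extraction/PCR1/PCR2 blanks.
    """

    n_lines: int = 19
    samples_per_arm: tuple[int, int] = (8, 12)      # uniform int range
    # sequencing depth: log-normal (natural-log params), bounded
    depth_log_mean: float = 9.0
    depth_log_sd: float = 1.1
    depth_min: int = 55
    depth_max: int = 93_394
    blank_depth_log_mean: float = 8.0
    blank_depth_log_sd: float = 0.8
    # spike-in
    spike_copies: float = 10_000.0
    homogenate_proportion: float = 0.2
    # treatment effect and biological variation
    treatment_fold: float = 15.0
    within_line_sd: float = 0.3                     # log10 copies
    line_log10_mean_range: tuple[float, float] = (5.0, 8.0)
    # community structure
    n_commensals_per_line: int = 12
    dominant_share_range: tuple[float, float] = (0.5, 0.95)
    dirichlet_concentration: float = 50.0
    # contamination and non-targets
    n_contaminants: int = 15
    contaminant_template: float = 500.0             # copies per library
    n_nontarget: int = 3
    nontarget_template: float = 200.0               # copies per specimen aliquot
    blanks: tuple[int, int, int] = (6, 7, 3)        # extraction, PCR1, PCR2
    spike_in_pcr_blanks: bool = False
    seed: int = 0

    def validate(self) -> None:
        if self.n_lines < 1 or self.n_commensals_per_line < 0:
            raise ValueError("need at least one line and non-negative commensals")
        if self.n_commensals_per_line == 0 and self.n_contaminants == 0:
            pass  # a dominant symbiont per line still exists
        if self.treatment_fold <= 0:
            raise ValueError("treatment_fold must be positive")
        if not 0 < self.homogenate_proportion <= 1:
            raise ValueError("homogenate_proportion must be in (0,1]")
        if self.spike_copies <= 0:
            raise ValueError("spike_copies must be positive")
        if self.samples_per_arm[0] < 1 or self.samples_per_arm[1] < self.samples_per_arm[0]:
            raise ValueError("invalid samples_per_arm range")
        if self.depth_min < 1 or self.depth_max < self.depth_min:
            raise ValueError("invalid depth bounds")

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v
                     for k, v in raw.items()})
        cfg.validate()
        return cfg

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                            for k, v in asdict(self).items()}, fh,
                           sort_keys=False)


@dataclass
class GroundTruth:
    """What the generator knows: the quantities the pipeline tries to recover."""

    true_copies: pd.Series                 # per experimental sample
    treatment_fold: float
    genotype_class: pd.Series              # symbiont/contaminant/spikein/nontarget
    line_of_sample: pd.Series
    treatment_of_sample: pd.Series
    template_proportions: pd.DataFrame = field(repr=False, default=None)


def _line_species(n_lines: int) -> list[tuple[str, str]]:
    """(line, species) labels; the first three species get two lines each."""
    out = []
    species_idx = 0
    i = 0
    while i < n_lines:
        species_idx += 1
        sp = f"species{species_idx:02d}"
        n_here = 2 if species_idx <= 3 and i + 1 < n_lines else 1
        for k in range(n_here):
            i += 1
            out.append((f"line{i:02d}", sp))
            if i == n_lines:
                break
    return out


def _draw_depth(rng, mu, sd, lo, hi, size):
    d = np.exp(rng.normal(mu, sd, size=size))
    return np.clip(np.round(d), lo, hi).astype(np.int64)


def simulate_experiment(config: SimulationConfig) -> tuple[ExperimentBundle, GroundTruth]:
    """Generate a complete experiment bundle plus its ground truth."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    lines = _line_species(config.n_lines)

    # --- genotype universe -------------------------------------------------
    genotypes, genera, true_class = [], {}, {}
    line_profiles = {}
    for li, (line, _) in enumerate(lines):
        ids = [f"{line}_sym{j:02d}" for j in range(1 + config.n_commensals_per_line)]
        genus_dom = _SYMBIONT_GENERA[li % len(_SYMBIONT_GENERA)]
        for j, gid in enumerate(ids):
            genotypes.append(gid)
            true_class[gid] = "symbiont"
            genera[gid] = (genus_dom if j == 0 else
                           _SYMBIONT_GENERA[(li + 3 + j) % len(_SYMBIONT_GENERA)])
        dom = rng.uniform(*config.dominant_share_range)
        if config.n_commensals_per_line:
            tail = rng.dirichlet(np.full(config.n_commensals_per_line, 1.0))
            profile = np.concatenate([[dom], (1 - dom) * tail])
        else:
            profile = np.array([1.0])
        line_profiles[line] = pd.Series(profile, index=ids)

    cont_ids = [f"cont{j:02d}" for j in range(config.n_contaminants)]
    for j, gid in enumerate(cont_ids):
        genotypes.append(gid)
        true_class[gid] = "contaminant"
        genera[gid] = _CONTAMINANT_GENERA[j % len(_CONTAMINANT_GENERA)]
    # fixed reagent profile: same lots across libraries, so shares are stable
    cont_profile = (rng.dirichlet(np.full(config.n_contaminants, 3.0))
                    if config.n_contaminants else np.array([]))

    nt_ids = [f"nontarget{j:02d}" for j in range(config.n_nontarget)]
    nt_flags = ["chloroplast", "mitochondria", "archaea"]
    for j, gid in enumerate(nt_ids):
        genotypes.append(gid)
        true_class[gid] = "nontarget"
    genotypes.append(SPIKE_ID)
    true_class[SPIKE_ID] = "spikein"

    # --- taxonomy ----------------------------------------------------------
    tax_rows = {}
    for gid in genotypes:
        cls = true_class[gid]
        if cls in ("symbiont", "contaminant"):
            tax_rows[gid] = {"domain": "Bacteria", "phylum": "", "class": "",
                             "order": "", "family": "", "genus": genera[gid],
                             "flags": frozenset()}
        elif cls == "nontarget":
            flag = nt_flags[nt_ids.index(gid) % len(nt_flags)]
            domain = "Archaea" if flag == "archaea" else "Eukaryota"
            tax_rows[gid] = {"domain": domain, "phylum": "", "class": "",
                             "order": "", "family": "", "genus": "",
                             "flags": frozenset({flag})}
        else:
            tax_rows[gid] = {"domain": "Bacteria", "phylum": "", "class": "",
                             "order": "", "family": "", "genus": "ArtificialTarget",
                             "flags": frozenset()}
    taxonomy = TaxonomyTable(pd.DataFrame.from_dict(tax_rows, orient="index"))

    # --- samples -----------------------------------------------------------
    metadata: list[SampleMetadata] = []
    columns: dict[str, np.ndarray] = {}
    template_cols: dict[str, np.ndarray] = {}
    true_copies, line_of, trt_of = {}, {}, {}
    gindex = pd.Index(genotypes)
    line_means = {line: rng.uniform(*config.line_log10_mean_range)
                  for line, _ in lines}
    line_size = {line: int(rng.integers(1, 6)) for line, _ in lines}

    def template_vector(bact: pd.Series | None, spike: float,
                        cont_level: float, nt_level: float) -> np.ndarray:
        t = pd.Series(0.0, index=gindex)
        if bact is not None:
            t.loc[bact.index] = bact.to_numpy()
        t.loc[SPIKE_ID] = spike
        if config.n_contaminants:
            t.loc[cont_ids] = cont_level * cont_profile
        if config.n_nontarget and nt_level > 0:
            t.loc[nt_ids] = nt_level / config.n_nontarget
        return t.to_numpy()

    for line, species in lines:
        for arm in ("control", "hotshot"):
            n = int(rng.integers(config.samples_per_arm[0],
                                 config.samples_per_arm[1] + 1))
            depths = _draw_depth(rng, config.depth_log_mean, config.depth_log_sd,
                                 config.depth_min, config.depth_max, n)
            for k in range(n):
                sid = f"{line}_{arm[:3]}{k + 1:02d}"
                a = 10 ** rng.normal(line_means[line], config.within_line_sd)
                if arm == "hotshot":
                    a /= config.treatment_fold
                comp = rng.dirichlet(
                    config.dirichlet_concentration
                    * line_profiles[line].to_numpy())
                bact = pd.Series(a * config.homogenate_proportion * comp,
                                 index=line_profiles[line].index)
                tvec = template_vector(bact, config.spike_copies,
                                       config.contaminant_template,
                                       config.nontarget_template)
                reads = rng.multinomial(depths[k], tvec / tvec.sum())
                columns[sid] = reads
                template_cols[sid] = tvec
                true_copies[sid], line_of[sid], trt_of[sid] = a, line, arm
                metadata.append(SampleMetadata(
                    sample_id=sid, role="experimental", species=species,
                    line=line, treatment=arm, size_class=line_size[line],
                    spike_copies_added=config.spike_copies,
                    homogenate_proportion=config.homogenate_proportion))

    blank_roles = ["blank_extraction", "blank_pcr1", "blank_pcr2"]
    for role, n_blanks in zip(blank_roles, config.blanks):
        for k in range(n_blanks):
            sid = f"{role}_{k + 1:02d}"
            depth = _draw_depth(rng, config.blank_depth_log_mean,
                                config.blank_depth_log_sd, config.depth_min,
                                config.depth_max, 1)[0]
            spike = (config.spike_copies
                     if role == "blank_extraction" or config.spike_in_pcr_blanks
                     else 0.0)
            tvec = template_vector(None, spike, config.contaminant_template, 0.0)
            if tvec.sum() == 0:
                tvec[gindex.get_loc(SPIKE_ID)] = 1.0  # degenerate config guard
            columns[sid] = rng.multinomial(depth, tvec / tvec.sum())
            template_cols[sid] = tvec
            metadata.append(SampleMetadata(sample_id=sid, role=role,
                                           batch=f"{role}_batch{k + 1}"))

    counts = GenotypeCountTable(pd.DataFrame(columns, index=gindex), level="zOTU")
    bundle = ExperimentBundle(counts=counts, taxonomy=taxonomy,
                              metadata=metadata,
                              spike_genotype_ids=frozenset({SPIKE_ID}))
    tprops = pd.DataFrame(template_cols, index=gindex)
    tprops = tprops.div(tprops.sum(axis=0), axis=1)
    truth = GroundTruth(
        true_copies=pd.Series(true_copies, name="true_copies"),
        treatment_fold=config.treatment_fold,
        genotype_class=pd.Series(true_class, name="class"),
        line_of_sample=pd.Series(line_of, name="line"),
        treatment_of_sample=pd.Series(trt_of, name="treatment"),
        template_proportions=tprops)
    return bundle, truth


# ---------------------------------------------------------------------------
# recovery diagnostics


@dataclass
class RecoveryReport:
    """Estimator errors and classifier confusion against the ground truth."""

    log10_copy_errors: pd.Series           # estimated − true, per sample
    median_abs_log10_error: float
    estimated_grand_fold: float | None
    grand_fold_ci95: tuple[float, float] | None
    true_fold: float
    confusion: pd.DataFrame                # true class × called class
    contaminant_sensitivity: float
    contaminant_specificity: float


def recovery_report(truth: GroundTruth, ledger, estimates,
                    fold_summary: dict | None = None) -> RecoveryReport:
    """Compare pipeline outputs with the generator's ground truth.

    Parameters
    ----------
    ledger : DecontamLedger
        The pipeline's genotype classification.
    estimates : list[AbundanceEstimate]
        Per-sample absolute abundance estimates.
    fold_summary : dict, optional
        Output of :func:`ampliquant.abundance.fold_change_summary`.
    """
    est = pd.Series({e.sample_id: e.copies_per_insect for e in estimates})
    common = est.index.intersection(truth.true_copies.index)
    if len(common) == 0:
        raise ValueError("no overlap between estimated and true sample sets")
    extra = est.index.difference(truth.true_copies.index)
    if len(extra):
        raise ValueError(f"estimates for samples unknown to truth: {list(extra[:5])}")
    pos = est[common] > 0
    errors = (np.log10(est[common][pos])
              - np.log10(truth.true_copies[common][pos]))

    called = ledger.frame["class"]
    true_cls = truth.genotype_class.reindex(called.index)
    confusion = pd.crosstab(true_cls, called, dropna=False)
    confusion.index.name, confusion.columns.name = "true", "called"
    n_cont = int((true_cls == "contaminant").sum())
    n_sym = int((true_cls == "symbiont").sum())
    sens = (float(((true_cls == "contaminant") & (called == "contaminant")).sum()
                  / n_cont) if n_cont else np.nan)
    spec = (float(((true_cls == "symbiont") & (called == "symbiont")).sum()
                  / n_sym) if n_sym else np.nan)
    return RecoveryReport(
        log10_copy_errors=errors,
        median_abs_log10_error=float(errors.abs().median()),
        estimated_grand_fold=(fold_summary or {}).get("grand_fold_geometric"),
        grand_fold_ci95=(fold_summary or {}).get("grand_fold_ci95"),
        true_fold=truth.treatment_fold,
        confusion=confusion,
        contaminant_sensitivity=sens,
        contaminant_specificity=spec)
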