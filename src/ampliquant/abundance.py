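"""Treatment-effect statistics on absolute microbial abundance.

Three views of the same question — does alkaline-lysis pre-treatment reduce
the amplifiable 16S template? —

* a global ANOVA of log10 copies on treatment across host lines, either with
  the line as a fixed factor (two-way, Type II sums of squares, no
  interaction) or as a random intercept (mixed model);
* per-group Kruskal-Wallis rank tests (per host line, or per body-size
  class), the non-parametric workhorse for small unbalanced arms;
* fold-change summaries: per-line ratios of geometric means and a grand
  (geometric-mean) fold across lines, with a t-interval on the log scale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .containers import SampleMetadata
from .quantify import AbundanceEstimate, estimates_frame


@dataclass
class TestResult:
    """One hypothesis-test outcome (rank test or permutation test)."""

    test_name: str
    grouping: str
    statistic: float
    p_value: float
    df: float | None = None
    permutations: int | None = None
    n_per_group: dict = field(default_factory=dict)
    effect_direction: int = 0
    note: str = ""

    def __post_init__(self):
        if not (np.isnan(self.p_value) or 0 <= self.p_value <= 1):
            raise ValueError(f"p_value out of [0,1]: {self.p_value}")

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def significance_stars(p: float) -> str:
    """Conventional significance marks: * <0.05, ** <0.01, *** <0.001."""
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class ModelFit:
    """A fitted abundance model with the treatment contrast extracted."""

    model: str
    formula: str
    params: pd.Series
    bse: pd.Series
    treatment_coef: float
    treatment_se: float
    treatment_ci: tuple[float, float]
    f_statistic: float
    p_value: float
    n_obs: int
    variance_components: dict | None = None

    def summary_row(self) -> dict:
        return {
            "model": self.model, "n": self.n_obs,
            "treatment_coef_log10": self.treatment_coef,
            "treatment_se": self.treatment_se,
            "ci_low": self.treatment_ci[0], "ci_high": self.treatment_ci[1],
            "F": self.f_statistic, "p": self.p_value,
            "stars": significance_stars(self.p_value),
        }


def _abundance_frame(estimates: list[AbundanceEstimate],
                     metadata: list[SampleMetadata]) -> pd.DataFrame:
    est = estimates_frame(estimates)
    meta = {m.sample_id: m for m in metadata}
    rows = []
    for sid, r in est.iterrows():
        m = meta[sid]
        rows.append({
            "sample_id": sid, "copies": r["copies_per_insect"],
            "log10_copies": (np.log10(r["copies_per_insect"])
                             if r["copies_per_insect"] > 0 else np.nan),
            "treatment": m.treatment, "line": m.line, "species": m.species,
            "size_class": m.size_class,
        })
    return pd.DataFrame(rows)


def log_abundance_model(
    estimates: list[AbundanceEstimate],
    metadata: list[SampleMetadata],
    model: str = "two_way_fixed",
    interaction: bool = False,
) -> ModelFit:
    """Fit log10 copies against treatment, accounting for the host line.

    ``two_way_fixed``: OLS with treatment and line as fixed factors; the
    treatment F uses Type II sums of squares. ``mixed_random_species``: a
    linear mixed model with a random intercept per line; the treatment test is
    the Wald test on the fixed coefficient. The treatment coefficient is the
    treated-minus-control difference in log10 copies (negative when the
    treatment depletes template); with a single line the fixed model reduces
    to a one-way ANOVA.

    Requires every estimate to be positive (zero-bacteria samples are excluded
    upstream by the sample filter).
    """
    df = _abundance_frame(estimates, metadata)
    if (df["copies"] <= 0).any():
        bad = df.loc[df["copies"] <= 0, "sample_id"].tolist()
        raise ValueError(f"non-positive copy estimates (exclude upstream): {bad}")
    n_lines = df["line"].nunique()
    if df["treatment"].nunique() < 2:
        raise ValueError("both treatment arms are required")
    trt = 'C(treatment, Treatment("control"))'
    key = f'{trt}[T.hotshot]'

    if model == "two_way_fixed":
        if interaction:
            cell_n = df.groupby(["line", "treatment"]).size()
            if (cell_n < 2).any():
                warnings.warn("cells with a single sample: interaction term "
                              "refused, fitting additive model", stacklevel=2)
                interaction = False
        rhs = f"{trt} * C(line)" if interaction else f"{trt} + C(line)"
        if n_lines < 2:
            rhs = trt  # degenerates to one-way ANOVA
        formula = f"log10_copies ~ {rhs}"
        fit = smf.ols(formula, data=df).fit()
        anova = sm.stats.anova_lm(fit, typ=2)
        f_stat = float(anova.loc[trt, "F"])
        p = float(anova.loc[trt, "PR(>F)"])
        ci = fit.conf_int().loc[key]
        return ModelFit(
            model="two_way_fixed", formula=formula, params=fit.params,
            bse=fit.bse, treatment_coef=float(fit.params[key]),
            treatment_se=float(fit.bse[key]),
            treatment_ci=(float(ci[0]), float(ci[1])),
            f_statistic=f_stat, p_value=p, n_obs=int(fit.nobs))
    if model == "mixed_random_species":
        if n_lines < 2:
            warnings.warn("single line: random-intercept model is degenerate; "
                          "prefer two_way_fixed", stacklevel=2)
        formula = f"log10_copies ~ {trt}"
        fit = smf.mixedlm(formula, data=df, groups=df["line"]).fit(reml=True)
        coef = float(fit.params[key])
        se = float(fit.bse[key])
        wald_f = (coef / se) ** 2
        p = float(fit.pvalues[key])
        ci = fit.conf_int().loc[key]
        return ModelFit(
            model="mixed_random_species", formula=formula, params=fit.params,
            bse=fit.bse, treatment_coef=coef, treatment_se=se,
            treatment_ci=(float(ci[0]), float(ci[1])),
            f_statistic=wald_f, p_value=p, n_obs=int(fit.nobs),
            variance_components={"line_var": float(fit.cov_re.iloc[0, 0]),
                                 "residual_var": float(fit.scale)})
    raise ValueError(f"unknown model {model!r}")


def kruskal_two_sample(control: np.ndarray, treated: np.ndarray) -> tuple[float, float, str]:
    """Tie-corrected Kruskal-Wallis H with chi-square p for two groups.

    All-tied data make H a 0/0; policy: H = 0, p = 1 with a tie note.
    """
    control = np.asarray(control, dtype=float)
    treated = np.asarray(treated, dtype=float)
    if len(np.unique(np.concatenate([control, treated]))) == 1:
        return 0.0, 1.0, "all observations tied"
    h, p = sps.kruskal(control, treated)
    return float(h), float(p), ""


def per_group_kruskal(
    estimates: list[AbundanceEstimate],
    metadata: list[SampleMetadata],
    group_by: str = "line",
) -> tuple[list[TestResult], list[tuple[str, str]]]:
    """Kruskal-Wallis treatment test on copies per insect, per group.

    ``group_by`` is ``line`` (host species × culture line) or ``size_class``.
    Groups with fewer than two samples or a single treatment arm are skipped
    with a reason. ``effect_direction`` is the sign of
    (median control − median treated): +1 when the treatment lowers abundance.
    """
    df = _abundance_frame(estimates, metadata)
    return kruskal_by_group(
        df.set_index("sample_id")["copies"], metadata, group_by=group_by,
        test_name="kruskal_copies")


def kruskal_by_group(
    values: pd.Series,
    metadata: list[SampleMetadata],
    group_by: str = "line",
    test_name: str = "kruskal",
) -> tuple[list[TestResult], list[tuple[str, str]]]:
    """Shared per-group Kruskal-Wallis kernel (abundance and alpha diversity).

    ``values`` is indexed by sample_id; grouping and treatment come from the
    metadata.
    """
    if group_by not in ("line", "size_class"):
        raise ValueError(f"unknown group_by {group_by!r}")
    meta = {m.sample_id: m for m in metadata}
    df = pd.DataFrame({
        "value": values,
        "group": [getattr(meta[s], group_by) for s in values.index],
        "treatment": [meta[s].treatment for s in values.index],
    })
    results, skipped = [], []
    for group, sub in df.groupby("group", sort=True):
        arms = sub.groupby("treatment")["value"]
        n_per = {t: int(len(v)) for t, v in arms}
        if len(sub) < 2 or len(n_per) < 2:
            reason = ("fewer than 2 samples" if len(sub) < 2
                      else "single treatment arm")
            skipped.append((str(group), reason))
            warnings.warn(f"group {group!r} skipped: {reason}", stacklevel=2)
            continue
        control = sub.loc[sub["treatment"] == "control", "value"].to_numpy()
        treated = sub.loc[sub["treatment"] == "hotshot", "value"].to_numpy()
        h, p, note = kruskal_two_sample(control, treated)
        direction = int(np.sign(np.median(control) - np.median(treated)))
        results.append(TestResult(
            test_name=test_name, grouping=str(group), statistic=h, p_value=p,
            df=1, n_per_group=n_per, effect_direction=direction, note=note))
    return results, skipped


def fold_change_summary(
    estimates: list[AbundanceEstimate],
    metadata: list[SampleMetadata],
    model_fit: ModelFit | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-line and grand fold changes of absolute abundance.

    Per line: (geometric mean of control copies) / (geometric mean of treated
    copies). Grand summaries, all reported:

    * ``grand_fold_geometric`` (default) — geometric mean of per-line folds,
      with a 95% t-interval on log10 folds across lines;
    * ``grand_fold_median`` — geometric mean of per-line median-based folds;
    * ``grand_fold_model`` — the back-transformed treatment coefficient, when
      a model fit is supplied.

    Lines with a missing arm are omitted from the table.
    """
    df = _abundance_frame(estimates, metadata)
    rows = []
    for line, sub in df.groupby("line", sort=True):
        byarm = sub.groupby("treatment")["log10_copies"]
        if {"control", "hotshot"} - set(byarm.groups):
            continue
        gm_c = byarm.get_group("control").mean()
        gm_t = byarm.get_group("hotshot").mean()
        med_c = sub.loc[sub["treatment"] == "control", "copies"].median()
        med_t = sub.loc[sub["treatment"] == "hotshot", "copies"].median()
        rows.append({
            "line": line,
            "n_control": int((sub["treatment"] == "control").sum()),
            "n_hotshot": int((sub["treatment"] == "hotshot").sum()),
            "fold_geometric": 10 ** (gm_c - gm_t),
            "fold_median": med_c / med_t if med_t > 0 else np.inf,
        })
    per_line = pd.DataFrame(rows)
    summary: dict = {}
    if len(per_line):
        logs = np.log10(per_line["fold_geometric"].to_numpy())
        grand = 10 ** logs.mean()
        summary["grand_fold_geometric"] = float(grand)
        if len(logs) > 1:
            se = logs.std(ddof=1) / np.sqrt(len(logs))
            tcrit = sps.t.ppf(0.975, len(logs) - 1)
            summary["grand_fold_ci95"] = (
                float(10 ** (logs.mean() - tcrit * se)),
                float(10 ** (logs.mean() + tcrit * se)))
        finite = per_line["fold_median"].replace(np.inf, np.nan).dropna()
        if len(finite):
            summary["grand_fold_median"] = float(
                10 ** np.log10(finite.to_numpy()).mean())
    if model_fit is not None:
        summary["grand_fold_model"] = float(10 ** (-model_fit.treatment_coef))
    return per_line, summary
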