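"""Community-composition statistics: rarefaction, alpha and beta diversity.

Alpha diversity is Shannon entropy on rarefied counts; beta diversity is
Bray-Curtis dissimilarity, ordinated by principal coordinate analysis (PCoA)
and tested by PERMANOVA (between-group location) and PERMDISP (between-group
dispersion). Each host line is analyzed separately so that between-species
differences cannot swamp the within-species treatment contrast.

Rarefaction is a single draw without replacement per sample to a common
depth (exactly the multivariate hypergeometric distribution), with the seed
recorded by the caller; diversity metrics are computed on rarefied tables
while all abundance statistics elsewhere use the original counts.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats as sps
from scipy.spatial.distance import pdist, squareform

from .abundance import TestResult, kruskal_by_group
from .containers import ExperimentBundle, GenotypeCountTable, SampleMetadata

# ---------------------------------------------------------------------------
# rarefaction


@dataclass
class RarefactionPlan:
    """A chosen rarefaction depth and what it costs."""

    depth: int
    n_samples_retained: int
    samples_lost: list
    expected_features_retained: float  # mean per retained sample


def choose_rarefaction_depth(
    table: GenotypeCountTable, min_sample_fraction: float = 0.8
) -> RarefactionPlan:
    """Largest depth keeping at least the given fraction of samples.

    The depth balances sample retention against reads (and hence features)
    retained; candidates are the observed library sizes. Also reports the
    samples that would be dropped and the expected number of features
    surviving subsampling per retained sample (hypergeometric survival
    probability summed over genotypes).
    """
    if not 0 < min_sample_fraction <= 1:
        raise ValueError("min_sample_fraction must be in (0, 1]")
    sizes = table.library_sizes
    if len(sizes) == 0:
        raise ValueError("empty table: no samples to rarefy")
    n = len(sizes)
    candidates = sorted(set(int(s) for s in sizes if s > 0), reverse=True)
    if not candidates:
        raise ValueError("all samples have zero reads")
    depth = None
    for d in candidates:
        if (sizes >= d).sum() / n >= min_sample_fraction:
            depth = d
            break
    if depth is None:
        depth = min(candidates)  # keep as many as possible
    lost = [s for s in table.sample_ids if sizes[s] < depth]
    kept = [s for s in table.sample_ids if sizes[s] >= depth]
    exp_feats = []
    for s in kept:
        col = table.counts[s].to_numpy()
        N = int(col.sum())
        surv = 1.0 - sps.hypergeom.pmf(0, N, col[col > 0], depth)
        exp_feats.append(float(np.sum(surv)))
    return RarefactionPlan(depth=int(depth), n_samples_retained=len(kept),
                           samples_lost=lost,
                           expected_features_retained=float(np.mean(exp_feats)))


def rarefy(table: GenotypeCountTable, depth: int, seed) -> GenotypeCountTable:
    """Subsample each sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads are dropped. A single draw per
    sample (multivariate hypergeometric); deterministic given the seed.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    sizes = table.library_sizes
    kept = [s for s in table.sample_ids if sizes[s] >= depth]
    if not kept:
        warnings.warn(f"no sample reaches depth {depth}; empty table returned",
                      stacklevel=2)
        return GenotypeCountTable(
            pd.DataFrame(index=table.counts.index, columns=[], dtype=np.int64),
            level=table.level)
    out = {}
    for s in kept:
        col = table.counts[s].to_numpy()
        out[s] = rng.multivariate_hypergeometric(col, depth)
    frame = pd.DataFrame(out, index=table.counts.index)
    return GenotypeCountTable(frame, level=table.level)


# ---------------------------------------------------------------------------
# alpha diversity


def shannon(counts, base: float = 2.0) -> float:
    """Shannon entropy −Σ p·log_base(p) of a count (or proportion) vector."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValueError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero vector has no defined entropy")
    p = x[x > 0] / total
    return float(-(p * (np.log(p) / np.log(base))).sum())


def shannon_per_sample(table: GenotypeCountTable, base: float = 2.0) -> pd.Series:
    vals = {s: shannon(table.counts[s].to_numpy(), base=base)
            for s in table.sample_ids if table.library_sizes[s] > 0}
    return pd.Series(vals, name="shannon")


def alpha_compare(
    table: GenotypeCountTable,
    metadata: list[SampleMetadata],
    group_by: str = "line",
    base: float = 2.0,
) -> tuple[list[TestResult], list[tuple[str, str]]]:
    """Per-group Kruskal-Wallis on per-sample Shannon entropy (rarefied input)."""
    values = shannon_per_sample(table, base=base)
    return kruskal_by_group(values, metadata, group_by=group_by,
                            test_name="kruskal_shannon")


# ---------------------------------------------------------------------------
# beta diversity


@dataclass
class DistanceMatrix:
    """Symmetric pairwise dissimilarities with a zero diagonal."""

    sample_ids: list
    data: np.ndarray

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        n = len(self.sample_ids)
        if self.data.shape != (n, n):
            raise ValueError("distance matrix shape does not match ids")
        if not np.allclose(self.data, self.data.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.data), 0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")
        if (self.data < -1e-12).any():
            raise ValueError("distances must be non-negative")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.data, index=self.sample_ids,
                            columns=self.sample_ids)


def bray_curtis(table: GenotypeCountTable) -> DistanceMatrix:
    """Bray-Curtis dissimilarity Σ|x−y| / Σ(x+y) between all sample pairs."""
    if table.shape[1] < 2:
        raise ValueError("need at least 2 samples")
    sizes = table.library_sizes
    zero = [s for s in table.sample_ids if sizes[s] == 0]
    if zero:
        raise ValueError(f"samples with zero total reads: {zero}")
    mat = table.counts.to_numpy(dtype=float).T  # samples x genotypes
    dm = squareform(pdist(mat, metric="braycurtis"))
    return DistanceMatrix(sample_ids=table.sample_ids, data=dm)


@dataclass
class OrdinationResult:
    """Principal coordinates: sample scores on positive-eigenvalue axes.

    Proportions explained are over positive eigenvalues only; negative
    eigenvalues (non-Euclidean input) are counted and reported, not corrected.
    """

    sample_ids: list
    coordinates: np.ndarray            # n_samples x n_positive_axes
    eigenvalues: np.ndarray            # all, decreasing
    proportion_explained: np.ndarray   # per positive axis
    n_negative_eigenvalues: int

    def coordinates_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.coordinates.shape[1])]
        return pd.DataFrame(self.coordinates, index=self.sample_ids,
                            columns=cols)


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical scaling (PCoA): eigendecomposition of the Gower-centered
    squared-distance matrix."""
    n = len(dm.sample_ids)
    if n < 2:
        raise ValueError("need at least 2 samples")
    b = _gower_center(dm.data ** 2)
    eigvals, eigvecs = np.linalg.eigh(b)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals).max()) if eigvals.size else 0.0
    pos = eigvals > tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    prop = eigvals[pos] / eigvals[pos].sum() if pos.any() else np.array([])
    return OrdinationResult(
        sample_ids=dm.sample_ids, coordinates=coords, eigenvalues=eigvals,
        proportion_explained=prop,
        n_negative_eigenvalues=int((eigvals < -tol).sum()))


def _codes(groups) -> tuple[np.ndarray, list]:
    labels = pd.Series(list(groups))
    cats = sorted(labels.unique())
    return labels.map({c: i for i, c in enumerate(cats)}).to_numpy(), cats


def _permanova_f(d2: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    n = d2.shape[0]
    ss_total = d2.sum() / (2 * n)
    ss_within = 0.0
    for g in range(n_groups):
        idx = np.flatnonzero(codes == g)
        ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
    ss_between = ss_total - ss_within
    df_between = n_groups - 1
    df_within = n - n_groups
    if ss_within <= 0:
        return np.inf if ss_between > 0 else 0.0
    return (ss_between / df_between) / (ss_within / df_within)


def _distinct_relabelings(codes: np.ndarray) -> "itertools.chain":
    """All distinct assignments of the multiset of group labels to positions."""
    n = len(codes)
    counts = np.bincount(codes)

    def rec(positions, counts):
        if not positions:
            yield ()
            return
        for g, c in enumerate(counts):
            if c > 0:
                counts2 = list(counts)
                counts2[g] -= 1
                for rest in rec(positions[1:], counts2):
                    yield (g,) + rest

    return rec(list(range(n)), list(counts))


def permanova(
    dm: DistanceMatrix,
    groups,
    permutations: int = 999,
    seed=None,
    mode: str = "sampled",
) -> TestResult:
    """Permutational multivariate ANOVA on a distance matrix.

    The pseudo-F compares between-group to within-group sums of squared
    distances; the p-value is the fraction of label relabelings with F at
    least the observed ((hits + 1)/(permutations + 1) for sampled
    permutations; the exact fraction over all distinct relabelings in
    ``mode="exhaustive"``). Ties count as ≥ observed (conservative).
    """
    codes, cats = _codes(groups)
    if len(cats) < 2:
        raise ValueError("PERMANOVA needs at least 2 groups")
    n_per = {c: int((codes == i).sum()) for i, c in enumerate(cats)}
    if min(n_per.values()) < 2:
        raise ValueError("every group needs at least 2 samples")
    d2 = dm.data ** 2
    f_obs = _permanova_f(d2, codes, len(cats))

    if mode == "exhaustive":
        fs = np.array([_permanova_f(d2, np.array(lab), len(cats))
                       for lab in _distinct_relabelings(codes)])
        p = float((fs >= f_obs - 1e-12).sum() / len(fs))
        n_perm = len(fs)
    elif mode == "sampled":
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(permutations):
            perm = rng.permutation(codes)
            if _permanova_f(d2, perm, len(cats)) >= f_obs - 1e-12:
                hits += 1
        p = (hits + 1) / (permutations + 1)
        n_perm = permutations
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return TestResult(test_name="permanova", grouping="+".join(map(str, cats)),
                      statistic=float(f_obs), p_value=float(p),
                      permutations=n_perm, n_per_group=n_per)


def centroid_distances(dm: DistanceMatrix, groups) -> np.ndarray:
    """Per-sample distance to its group centroid in full PCoA space.

    Axes with negative eigenvalues contribute negatively to the squared
    distance (imaginary coordinates), so squared terms are subtracted on
    those axes and the total clipped at zero before the square root.
    """
    codes, cats = _codes(groups)
    b = _gower_center(dm.data ** 2)
    eigvals, eigvecs = np.linalg.eigh(b)
    tol = max(1e-10, 1e-10 * abs(eigvals).max()) if eigvals.size else 0.0
    pos, neg = eigvals > tol, eigvals < -tol
    real = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    imag = eigvecs[:, neg] * np.sqrt(-eigvals[neg])
    d2 = np.zeros(len(codes))
    for g in range(len(cats)):
        idx = codes == g
        d2[idx] += ((real[idx] - real[idx].mean(axis=0)) ** 2).sum(axis=1)
        if imag.shape[1]:
            d2[idx] -= ((imag[idx] - imag[idx].mean(axis=0)) ** 2).sum(axis=1)
    return np.sqrt(np.clip(d2, 0, None))


def _anova_f(values: np.ndarray, codes: np.ndarray, n_groups: int) -> float:
    grand = values.mean()
    ss_between = ss_within = 0.0
    for g in range(n_groups):
        v = values[codes == g]
        ss_between += len(v) * (v.mean() - grand) ** 2
        ss_within += ((v - v.mean()) ** 2).sum()
    df_b, df_w = n_groups - 1, len(values) - n_groups
    if ss_within <= 0:
        return np.inf if ss_between > 1e-300 else 0.0
    return (ss_between / df_b) / (ss_within / df_w)


def permdisp(
    dm: DistanceMatrix,
    groups,
    permutations: int = 999,
    seed=None,
) -> TestResult:
    """Homogeneity-of-dispersions test: one-way ANOVA F on distances to group
    centroids, with a permutation p-value (labels permuted over the computed
    distances)."""
    codes, cats = _codes(groups)
    if len(cats) < 2:
        raise ValueError("PERMDISP needs at least 2 groups")
    n_per = {c: int((codes == i).sum()) for i, c in enumerate(cats)}
    if min(n_per.values()) < 2:
        raise ValueError("every group needs at least 2 samples")
    dists = centroid_distances(dm, groups)
    f_obs = _anova_f(dists, codes, len(cats))
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(permutations):
        perm = rng.permutation(codes)
        if _anova_f(dists, perm, len(cats)) >= f_obs - 1e-12:
            hits += 1
    p = (hits + 1) / (permutations + 1)
    return TestResult(test_name="permdisp", grouping="+".join(map(str, cats)),
                      statistic=float(f_obs), p_value=float(p),
                      permutations=permutations, n_per_group=n_per)


# ---------------------------------------------------------------------------
# taxonomic summaries


def genus_aggregate(
    table: GenotypeCountTable,
    taxonomy,
    min_mean_relabund: float = 0.05,
) -> pd.DataFrame:
    """Genus × sample relative abundances with low-abundance genera pooled.

    Counts are summed by genus (genotypes lacking a genus label pooled under
    ``unclassified`` before thresholding); genera whose mean relative
    abundance across samples falls below the threshold are pooled into an
    ``other`` bin, which is always present (possibly all-zero). Columns of
    samples with reads sum to 1.
    """
    if not 0 <= min_mean_relabund < 1:
        raise ValueError("min_mean_relabund must be in [0, 1)")
    genus = pd.Series(
        {g: (taxonomy.genus_of(g) or "unclassified") for g in table.genotype_ids})
    by_genus = table.counts.groupby(genus).sum()
    totals = by_genus.sum(axis=0).astype(float)
    rel = by_genus.div(totals.where(totals > 0), axis=1).fillna(0.0)
    keep = rel.mean(axis=1) >= min_mean_relabund
    top = rel.loc[keep].sort_index()
    other = rel.loc[~keep].sum(axis=0)
    other.name = "other"
    return pd.concat([top, other.to_frame().T])


def genus_shift_table(
    control_rel: pd.DataFrame, treated_rel: pd.DataFrame
) -> pd.DataFrame:
    """Mean per-genus relative abundance per arm and the treated − control
    shift (for above-threshold genera)."""
    mc = control_rel.mean(axis=1)
    mt = treated_rel.mean(axis=1)
    genera = sorted(set(mc.index) | set(mt.index))
    out = pd.DataFrame({
        "mean_control": mc.reindex(genera).fillna(0.0),
        "mean_hotshot": mt.reindex(genera).fillna(0.0),
    })
    out["shift"] = out["mean_hotshot"] - out["mean_control"]
    return out


# ---------------------------------------------------------------------------
# per-line beta report


@dataclass
class LineBetaResult:
    """Beta-diversity outcome for one host line."""

    line: str
    n_control: int
    n_hotshot: int
    rarefaction_depth: int
    permanova: TestResult
    permdisp: TestResult
    ordination: OrdinationResult


def per_line_beta_report(
    decontaminated: GenotypeCountTable,
    metadata: list[SampleMetadata],
    sample_ids: list | None = None,
    permutations: int = 999,
    seed: int = 0,
    min_sample_fraction: float = 0.8,
) -> tuple[list[LineBetaResult], list[tuple[str, str]]]:
    """Per-line Bray-Curtis / PCoA / PERMANOVA / PERMDISP between treatments.

    Each line is subset, rarefied to its own depth (chosen to retain at least
    ``min_sample_fraction`` of its samples), stripped of all-zero genotypes,
    then tested. Lines with fewer than 2 samples per arm (after rarefaction)
    are skipped with a reason. Deterministic given the seed.
    """
    meta = {m.sample_id: m for m in metadata}
    if sample_ids is None:
        sample_ids = [s for s in decontaminated.sample_ids
                      if not meta[s].is_blank]
    by_line: dict[str, list] = {}
    for s in sample_ids:
        by_line.setdefault(meta[s].line, []).append(s)
    results, skipped = [], []
    ss = np.random.SeedSequence(seed)
    child_seeds = {line: s for line, s in
                   zip(sorted(by_line), ss.spawn(2 * len(by_line)))}
    for line in sorted(by_line):
        samples = by_line[line]
        sub = decontaminated.subset_samples(samples)
        arms = pd.Series({s: meta[s].treatment for s in sub.sample_ids})
        if min(((arms == "control").sum(), (arms == "hotshot").sum())) < 2:
            skipped.append((line, "fewer than 2 samples in an arm"))
            continue
        plan = choose_rarefaction_depth(sub, min_sample_fraction)
        rare = rarefy(sub, plan.depth, child_seeds[line]).drop_zero_genotypes()
        arms = pd.Series({s: meta[s].treatment for s in rare.sample_ids})
        if min(((arms == "control").sum(), (arms == "hotshot").sum())) < 2:
            skipped.append((line, "fewer than 2 samples per arm after rarefaction"))
            continue
        dm = bray_curtis(rare)
        labels = [meta[s].treatment for s in rare.sample_ids]
        perm_seed = int(np.random.default_rng(child_seeds[line]).integers(2**31))
        results.append(LineBetaResult(
            line=line,
            n_control=int((arms == "control").sum()),
            n_hotshot=int((arms == "hotshot").sum()),
            rarefaction_depth=plan.depth,
            permanova=permanova(dm, labels, permutations=permutations,
                                seed=perm_seed),
            permdisp=permdisp(dm, labels, permutations=permutations,
                              seed=perm_seed + 1),
            ordination=pcoa(dm)))
    return results, skipped
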