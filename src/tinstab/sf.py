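"""Association between splicing-factor expression and transcriptome instability.

Per-gene Pearson correlation of log2 expression with the per-sample total
relative amount of deviating exon usage, benchmarked two ways:

* random gene sets of equal size drawn from the whole platform, summarized
  by their counts of significant genes, mean significant r, and
  negative:positive ratio;
* a permutation null obtained by shuffling the deviation-amount vector
  across samples, summarized by the median correlation over the gene set.

Hierarchical clustering of samples on splicing-factor expression
(Euclidean distance, complete linkage by default) with a two-group cut at
the dendrogram root, tested for association with oTIN direction by
Fisher's exact test.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .io import ValidationError

logger = logging.getLogger("tinstab")

__all__ = [
    "CorrelationResult", "correlate_genes", "compare_mean_r",
    "RandomSetNull", "random_geneset_null",
    "PermutationNull", "permutation_null",
    "ClusterPartition", "hierarchical_cluster", "cluster_association",
    "SplicingFactorModel", "SplicingFactorResults",
]


def _align(expr: pd.DataFrame, rel_total: pd.Series) -> tuple[pd.DataFrame, np.ndarray]:
    if set(expr.columns) != set(rel_total.index):
        raise ValidationError("expression samples and rel_total samples differ")
    if expr.shape[1] < 3:
        raise ValidationError("need at least 3 samples for correlation")
    return expr, rel_total.reindex(expr.columns).to_numpy(dtype=float)


def _pearson_matrix(values: np.ndarray, y: np.ndarray
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of ``values`` against ``y`` with t-based p-values."""
    n = values.shape[1]
    xz = values - values.mean(axis=1, keepdims=True)
    yz = y - y.mean()
    denom = np.sqrt((xz**2).sum(axis=1) * (yz**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (xz @ yz) / denom
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return r, p


@dataclass
class CorrelationResult:
    """Per-gene Pearson correlations to deviating exon usage amounts."""

    table: pd.DataFrame                 # columns r, p, significant
    alpha: float
    excluded: list[str] = field(default_factory=list)  # zero-variance genes

    @property
    def n_genes(self) -> int:
        return len(self.table)

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())

    @property
    def n_negative_significant(self) -> int:
        return int((self.table["significant"] & (self.table["r"] < 0)).sum())

    @property
    def n_positive_significant(self) -> int:
        return int((self.table["significant"] & (self.table["r"] > 0)).sum())

    @property
    def significant_r(self) -> np.ndarray:
        return self.table.loc[self.table["significant"], "r"].to_numpy()

    @property
    def mean_r_significant(self) -> float:
        r = self.significant_r
        return float(r.mean()) if r.size else float("nan")

    @property
    def median_r(self) -> float:
        return float(self.table["r"].median())

    def summary(self) -> str:
        return "\n".join([
            f"correlation of {self.n_genes} genes with deviating exon usage "
            f"(alpha {self.alpha})",
            f"  significant: {self.n_significant} "
            f"({100 * self.n_significant / max(self.n_genes, 1):.1f}%)",
            f"  negative / positive among significant: "
            f"{self.n_negative_significant} / {self.n_positive_significant}",
            f"  mean r among significant: {self.mean_r_significant:.3f}",
            f"  median r over all genes : {self.median_r:.3f}",
        ] + ([f"  excluded (zero variance): {len(self.excluded)}"]
             if self.excluded else []))


def correlate_genes(expr: pd.DataFrame, rel_total: pd.Series,
                    alpha: float = 0.05) -> CorrelationResult:
    """Pearson r and two-sided p (t distribution, n-2 df) per gene.

    Genes with zero expression variance are excluded with a logged count.
    """
    expr, y = _align(expr, rel_total)
    values = expr.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    excluded = list(expr.index[~variable])
    if excluded:
        logger.info("correlate_genes: excluding %d constant gene(s)", len(excluded))
    if y.std() == 0:
        raise ValidationError("rel_total has zero variance across samples")
    r, p = _pearson_matrix(values[variable], y)
    table = pd.DataFrame({"r": r, "p": p, "significant": p < alpha},
                         index=expr.index[variable])
    res = CorrelationResult(table=table, alpha=alpha, excluded=excluded)
    logger.info("correlate_genes: %d of %d significant (%d negative)",
                res.n_significant, res.n_genes, res.n_negative_significant)
    return res


def compare_mean_r(group_a: np.ndarray, group_b: np.ndarray) -> tuple[float, float]:
    """Equal-variance two-sample t test for equality of mean correlations."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("both groups need at least 2 values")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return float(t), float(p)


@dataclass
class RandomSetNull:
    """Correlation summaries for random gene sets of the same size."""

    table: pd.DataFrame     # per set: n_significant, mean_r_significant,
                            #          n_negative, n_positive, neg_pos_ratio
    set_size: int
    alpha: float
    significant_r: list[np.ndarray] = field(default_factory=list)

    @property
    def n_sets(self) -> int:
        return len(self.table)

    def p_count(self, observed_n_significant: int) -> float:
        """Fraction of random sets with >= as many significant genes."""
        return float((self.table["n_significant"] >= observed_n_significant).mean())

    def p_ratio(self, observed_ratio: float) -> float:
        """Fraction of random sets with >= as extreme a negative:positive ratio."""
        return float((self.table["neg_pos_ratio"] >= observed_ratio).mean())

    def pooled_significant_r(self) -> np.ndarray:
        if not self.significant_r:
            return np.empty(0)
        return np.concatenate(self.significant_r)


def random_geneset_null(expr_all: pd.DataFrame, rel_total: pd.Series,
                        n_sets: int = 100, set_size: int = 280,
                        seed: int | None = None,
                        rng: np.random.Generator | None = None,
                        alpha: float = 0.05,
                        exclude: list[str] | None = None) -> RandomSetNull:
    """Summaries of ``n_sets`` random gene sets sampled without replacement.

    By default sets are drawn from all genes on the platform (splicing
    factors included); pass ``exclude`` to remove genes from the pool.
    Reproducible given the seed.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    pool_expr = expr_all.drop(index=exclude, errors="ignore") if exclude else expr_all
    base = correlate_genes(pool_expr, rel_total, alpha)
    genes = base.table.index.to_numpy()
    if set_size > len(genes):
        raise ValidationError(
            f"set_size {set_size} exceeds the {len(genes)} usable genes")
    rows = []
    sig_rs = []
    for _ in range(n_sets):
        members = rng.choice(genes, size=set_size, replace=False)
        sub = base.table.loc[members]
        sig = sub[sub["significant"]]
        n_neg = int((sig["r"] < 0).sum())
        n_pos = int((sig["r"] > 0).sum())
        ratio = np.nan if len(sig) == 0 else (np.inf if n_pos == 0 else n_neg / n_pos)
        rows.append({
            "n_significant": len(sig),
            "mean_r_significant": sig["r"].mean() if len(sig) else np.nan,
            "n_negative": n_neg,
            "n_positive": n_pos,
            "neg_pos_ratio": ratio,
        })
        sig_rs.append(sig["r"].to_numpy())
    table = pd.DataFrame(rows, index=pd.RangeIndex(n_sets, name="set"))
    logger.info("random sets: n_significant mean %.1f (range %d to %d) of %d",
                table["n_significant"].mean(), table["n_significant"].min(),
                table["n_significant"].max(), set_size)
    return RandomSetNull(table=table, set_size=set_size, alpha=alpha,
                         significant_r=sig_rs)


@dataclass
class PermutationNull:
    """Correlation summaries under permutation of the deviation amounts."""

    table: pd.DataFrame         # per permutation: median_r, n_neg_sig, n_pos_sig
    observed_median_r: float
    observed_neg_sig: int
    observed_pos_sig: int
    p_median_r: float           # one-sided on |median r|, add-one rule
    p_neg_excess: float         # fraction of perms with neg-pos excess >= observed

    @property
    def n_perm(self) -> int:
        return len(self.table)

    def summary(self) -> str:
        return "\n".join([
            f"permutation null ({self.n_perm} permutations)",
            f"  observed median r: {self.observed_median_r:.3f} "
            f"(perm range {self.table['median_r'].min():.3f} to "
            f"{self.table['median_r'].max():.3f})",
            f"  empirical p (|median r|, one-sided): {self.p_median_r:.4g}",
            f"  fraction of perms with neg-pos excess >= observed: "
            f"{self.p_neg_excess:.4g}",
        ])


def permutation_null(expr_sf: pd.DataFrame, rel_total: pd.Series,
                     n_perm: int = 1000, seed: int | None = None,
                     rng: np.random.Generator | None = None,
                     alpha: float = 0.05) -> PermutationNull:
    """Shuffle the deviation-amount vector across samples ``n_perm`` times.

    For each permutation the median Pearson r over all genes of the set and
    the counts of significantly negative/positive genes are recorded.  The
    empirical p for the observed median r uses the add-one rule
    (1 + #{|median r_perm| >= |observed|}) / (n_perm + 1).
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    if rng is None:
        rng = np.random.default_rng(seed)
    expr_sf, y = _align(expr_sf, rel_total)
    values = expr_sf.to_numpy(dtype=float)
    variable = values.std(axis=1) > 0
    values = values[variable]
    r_obs, p_obs = _pearson_matrix(values, y)
    obs_median = float(np.median(r_obs))
    obs_neg = int(((p_obs < alpha) & (r_obs < 0)).sum())
    obs_pos = int(((p_obs < alpha) & (r_obs > 0)).sum())

    n = y.size
    perms = np.empty((n_perm, n), dtype=float)
    for i in range(n_perm):
        perms[i] = y[rng.permutation(n)]
    # row-standardize once; a permutation of y permutes its z-scores
    xz = values - values.mean(axis=1, keepdims=True)
    xnorm = np.sqrt((xz**2).sum(axis=1))
    yz = perms - perms.mean(axis=1, keepdims=True)
    ynorm = np.sqrt((yz**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.clip((xz @ yz.T) / np.outer(xnorm, ynorm), -1, 1)  # genes x perms
        t = r * np.sqrt((n - 2) / (1 - r**2))
    p = 2 * stats.t.sf(np.abs(t), df=n - 2)
    median_r = np.median(r, axis=0)
    n_neg = ((p < alpha) & (r < 0)).sum(axis=0)
    n_pos = ((p < alpha) & (r > 0)).sum(axis=0)
    table = pd.DataFrame({"median_r": median_r, "n_neg_sig": n_neg,
                          "n_pos_sig": n_pos},
                         index=pd.RangeIndex(n_perm, name="perm"))
    p_median = float((1 + (np.abs(median_r) >= abs(obs_median)).sum()) / (n_perm + 1))
    p_excess = float(((n_neg - n_pos) >= (obs_neg - obs_pos)).mean())
    logger.info("permutation null: median r range [%.3f, %.3f], observed %.3f, p %.4g",
                median_r.min(), median_r.max(), obs_median, p_median)
    return PermutationNull(table=table, observed_median_r=obs_median,
                           observed_neg_sig=obs_neg, observed_pos_sig=obs_pos,
                           p_median_r=p_median, p_neg_excess=p_excess)


@dataclass
class ClusterPartition:
    """Two-group sample partition from agglomerative clustering."""

    linkage_matrix: np.ndarray
    labels: pd.Series           # sample -> group in {1, 2}
    metric: str
    linkage: str

    @property
    def groups(self) -> dict[int, list[str]]:
        return {g: list(self.labels.index[self.labels == g]) for g in (1, 2)}


def hierarchical_cluster(expr_sf: pd.DataFrame, metric: str = "euclidean",
                         linkage: str = "complete", center: bool = True,
                         restrict_to: list[str] | None = None) -> ClusterPartition:
    """Cluster samples on splicing-factor expression; cut the root into 2.

    Expression is median-centered per gene before the distance computation
    (``center=False`` disables).  Samples are ordered lexicographically
    before linkage so tie-breaking is deterministic.
    """
    if restrict_to is not None:
        missing = set(restrict_to) - set(expr_sf.columns)
        if missing:
            raise ValidationError(f"restrict_to sample(s) not in expression: "
                                  f"{sorted(missing)[:5]}")
        expr_sf = expr_sf[list(restrict_to)]
    if expr_sf.shape[1] < 2:
        raise ValidationError("need at least 2 samples to cluster")
    expr_sf = expr_sf[sorted(expr_sf.columns)]
    x = expr_sf.to_numpy(dtype=float)
    if center:
        x = x - np.median(x, axis=1, keepdims=True)
    samples = x.T  # observations are samples
    Z = hierarchy.linkage(pdist(samples, metric=metric), method=linkage)
    labels = hierarchy.fcluster(Z, t=2, criterion="maxclust")
    out = pd.Series(labels, index=expr_sf.columns, name="cluster")
    logger.info("clustering (%s, %s): groups of %d and %d samples",
                metric, linkage, int((out == 1).sum()), int((out == 2).sum()))
    return ClusterPartition(linkage_matrix=Z, labels=out, metric=metric,
                            linkage=linkage)


def cluster_association(partition: ClusterPartition, profiles: pd.DataFrame,
                        otin_only: bool = False) -> tuple[pd.DataFrame, float]:
    """Fisher's exact test of cluster membership vs oTIN direction.

    Direction is the sign of rel_total: above (+) or below (-) the cohort
    average amount of deviating exon usage.  With ``otin_only`` the table is
    restricted to oTIN-called samples (the clustering itself should then
    have been run on the same subset).
    """
    samples = partition.labels.index
    missing = samples.difference(profiles.index)
    if len(missing):
        raise ValidationError(f"profiles missing for clustered sample(s): "
                              f"{list(missing)[:5]}")
    prof = profiles.loc[samples]
    if otin_only:
        keep = prof["is_oTIN"]
        prof = prof[keep]
    direction = np.where(prof["rel_total"] > 0, "high", "low")
    labels = partition.labels.loc[prof.index]
    table = pd.crosstab(labels, pd.Series(direction, index=prof.index, name="oTIN"))
    table = table.reindex(index=[1, 2], columns=["low", "high"], fill_value=0)
    _, p = stats.fisher_exact(table.to_numpy())
    return table, float(p)


class SplicingFactorModel:
    """Association of a splicing-factor gene set with deviation burden.

    Parameters
    ----------
    expression : DataFrame
        Gene-level log2 expression (all genes on the platform x samples).
    rel_total : Series
        Per-sample total relative amount of deviating exon usage.
    sf_genes : list of str
        The splicing-factor gene set; members absent from the expression
        matrix are an error (reported, never silently dropped).
    """

    def __init__(self, expression: pd.DataFrame, rel_total: pd.Series,
                 sf_genes: list[str]):
        missing = [g for g in sf_genes if g not in expression.index]
        if missing:
            raise ValidationError(
                f"{len(missing)} splicing-factor gene(s) absent from the "
                f"expression matrix, e.g. {missing[:5]}"
            )
        self.expression = expression
        self.rel_total = rel_total
        self.sf_genes = list(sf_genes)

    def fit(self, alpha: float = 0.05, n_random_sets: int = 100,
            set_size: int | None = None, n_perm: int = 1000,
            seed: int | None = None,
            exclude_sf_from_random: bool = False) -> "SplicingFactorResults":
        rng = np.random.default_rng(seed)
        if set_size is None:
            set_size = len(self.sf_genes)
        sf_corr = correlate_genes(self.expression.loc[self.sf_genes],
                                  self.rel_total, alpha)
        random_null = random_geneset_null(
            self.expression, self.rel_total, n_sets=n_random_sets,
            set_size=set_size, rng=rng, alpha=alpha,
            exclude=self.sf_genes if exclude_sf_from_random else None)
        perm_null = permutation_null(self.expression.loc[self.sf_genes],
                                     self.rel_total, n_perm=n_perm, rng=rng,
                                     alpha=alpha)
        pooled = random_null.pooled_significant_r()
        if sf_corr.significant_r.size >= 2 and pooled.size >= 2:
            t_mean_r, p_mean_r = compare_mean_r(sf_corr.significant_r, pooled)
        else:
            t_mean_r, p_mean_r = float("nan"), float("nan")
        sig = sf_corr
        ratio = (np.inf if sig.n_positive_significant == 0
                 else sig.n_negative_significant / sig.n_positive_significant)
        return SplicingFactorResults(
            correlations=sf_corr, random_null=random_null,
            permutation=perm_null,
            p_count_vs_random=random_null.p_count(sf_corr.n_significant),
            p_ratio_vs_random=random_null.p_ratio(ratio),
            t_mean_r_vs_random=t_mean_r, p_mean_r_vs_random=p_mean_r,
        )


@dataclass
class SplicingFactorResults:
    correlations: CorrelationResult
    random_null: RandomSetNull
    permutation: PermutationNull
    p_count_vs_random: float
    p_ratio_vs_random: float
    t_mean_r_vs_random: float
    p_mean_r_vs_random: float

    def summary(self) -> str:
        rn = self.random_null
        def fmt_p(p: float) -> str:
            return f"< {1 / rn.n_sets:g}" if p == 0 else f"{p:g}"
        return "\n".join([
            self.correlations.summary(),
            f"random-set null ({rn.n_sets} sets of {rn.set_size}):",
            f"  significant genes per set: mean {rn.table['n_significant'].mean():.1f} "
            f"(range {int(rn.table['n_significant'].min())} to "
            f"{int(rn.table['n_significant'].max())})",
            f"  p (count >= splicing factors)  : {fmt_p(self.p_count_vs_random)}",
            f"  p (neg:pos ratio >= observed)  : {fmt_p(self.p_ratio_vs_random)}",
            f"  mean-r t test vs random sets   : t = {self.t_mean_r_vs_random:.3f}, "
            f"p = {self.p_mean_r_vs_random:.3g}",
            self.permutation.summary(),
        ])
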