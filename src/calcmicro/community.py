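"""Community-level statistics: alpha diversity with ANOVA/Tukey, sequential
PERMANOVA, pairwise PERMANOVA with FDR, PCoA, group-prevalence filtering and
generic two-group tests.

The PERMANOVA here is the sequential (Type-I) ``adonis``-style partitioning:
with ``G`` the Gower-centred matrix of squared distances, the sum of squares
attributed to term *t* is ``tr(H_t G) - tr(H_{t-1} G)`` where ``H_t`` is the
hat matrix of the cumulative design through term *t*.  The pseudo-F for each
term is tested by unrestricted permutation of the rows/columns of the distance
matrix.  Term order therefore matters and follows the order given by the
caller (e.g. read count, then dataset, then subspecies).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from skbio.diversity import alpha as skbio_alpha
from statsmodels.stats.multitest import multipletests

from .tables import DistanceMatrix, FeatureTable, SampleMetadata


# ---------------------------------------------------------------------------
# Alpha diversity
# ---------------------------------------------------------------------------

def _check_counts(counts) -> np.ndarray:
    c = np.asarray(counts)
    if c.ndim != 1 or (c < 0).any():
        raise ValueError("counts must be a 1-D nonnegative vector")
    if not (c > 0).any():
        raise ValueError("all-zero sample has no diversity")
    return c


def chao1(counts, bias_corrected: bool = True) -> float:
    """Chao1 richness; bias-corrected form ``S + F1(F1-1)/(2(F2+1))`` by default."""
    c = _check_counts(counts)
    return float(skbio_alpha.chao1(c.astype(int), bias_corrected=bias_corrected))


def shannon(counts) -> float:
    """Shannon index ``-sum p_i ln p_i`` (natural log)."""
    c = _check_counts(counts)
    return float(skbio_alpha.shannon(c.astype(int), base=math.e))


def rarefy(counts, depth: int, seed: int = 0) -> np.ndarray:
    """Subsample a count vector without replacement to ``depth`` reads."""
    c = np.asarray(counts, dtype=np.int64)
    total = int(c.sum())
    if depth > total:
        raise ValueError("rarefaction depth exceeds sample depth")
    rng = np.random.default_rng(seed)
    return rng.multivariate_hypergeometric(c, depth)


def alpha_diversity(
    table: FeatureTable | pd.DataFrame, rarefy_to: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Per-sample Chao1 and Shannon values.

    ``rarefy_to`` optionally subsamples every sample to a common depth first
    (one way to normalise richness for unequal sequencing effort); it is off by
    default and flagged in the output through the ``rarefied_depth`` attribute
    column.
    """
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    rows = {}
    for i, sample in enumerate(counts.columns):
        c = counts[sample].values
        if rarefy_to is not None:
            c = rarefy(c, rarefy_to, seed=seed + i)
        rows[sample] = dict(chao1=chao1(c), shannon=shannon(c))
    out = pd.DataFrame(rows).T
    out["rarefied_depth"] = rarefy_to if rarefy_to is not None else np.nan
    return out


@dataclass
class AlphaAnovaResult:
    """One-way ANOVA (optionally on transformed values) plus Tukey contrasts."""

    transform: str | None
    anova_table: pd.DataFrame
    tukey: pd.DataFrame

    @property
    def f(self) -> float:
        return float(self.anova_table.loc["group", "F"])

    @property
    def pvalue(self) -> float:
        return float(self.anova_table.loc["group", "p"])

    def summary(self) -> str:
        return (
            f"One-way ANOVA ({'transform: ' + self.transform if self.transform else 'untransformed'})\n"
            + self.anova_table.to_string()
            + "\n\nTukey HSD\n"
            + self.tukey.to_string(index=False)
        )


def alpha_anova(
    values: pd.Series, groups: pd.Series, transform: str | None = None
) -> AlphaAnovaResult:
    """ANOVA of alpha-diversity values across groups with Tukey posthoc tests.

    ``transform`` may be ``"sqrt500"`` (``sqrt(500 - x)``, used for Chao1 and
    requiring all values < 500), ``"exp"`` (used for Shannon) or ``None``.
    Tukey adjusted p-values are additionally BH-corrected across pairs
    (``p_fdr``).
    """
    values = pd.Series(values).astype(float)
    groups = pd.Series(groups).reindex(values.index)
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("at least two groups are required")
    if (sizes < 2).any():
        small = list(sizes.index[sizes < 2])
        raise ValueError(f"group(s) with fewer than 2 samples: {small}")
    if transform == "sqrt500":
        if (values >= 500).any():
            bad = list(values.index[values >= 500])
            raise ValueError(
                f"sqrt(500 - x) transform undefined for values >= 500: {bad}"
            )
        y = np.sqrt(500.0 - values)
    elif transform == "exp":
        y = np.exp(values)
    elif transform is None:
        y = values.copy()
    else:
        raise ValueError(f"unknown transform {transform!r}")

    grand = y.mean()
    ssb = sum(len(v) * (v.mean() - grand) ** 2 for _, v in y.groupby(groups))
    ssw = sum(((v - v.mean()) ** 2).sum() for _, v in y.groupby(groups))
    df_b = len(sizes) - 1
    df_w = len(y) - len(sizes)
    if ssb <= 1e-300 and ssw <= 1e-300:
        f, p = 0.0, 1.0
    elif ssw <= 1e-300:
        f, p = np.inf, 0.0
    else:
        f = (ssb / df_b) / (ssw / df_w)
        p = float(stats.f.sf(f, df_b, df_w))
    anova_table = pd.DataFrame(
        {
            "df": [df_b, df_w],
            "sum_sq": [ssb, ssw],
            "mean_sq": [ssb / df_b, ssw / df_w if df_w else np.nan],
            "F": [f, np.nan],
            "p": [p, np.nan],
        },
        index=["group", "residual"],
    )

    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    tk = pairwise_tukeyhsd(y.values, groups.values)
    tukey = pd.DataFrame(
        tk.summary().data[1:], columns=[str(c) for c in tk.summary().data[0]]
    )
    tukey["p-adj"] = tukey["p-adj"].astype(float)
    tukey["p_fdr"] = multipletests(tukey["p-adj"].values, method="fdr_bh")[1]
    return AlphaAnovaResult(transform, anova_table, tukey)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    n = a.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def _term_columns(series: pd.Series, term: str) -> np.ndarray:
    if series.isna().any():
        raise ValueError(f"term {term!r} has missing values")
    if series.dtype.kind in "OUSb" or isinstance(series.dtype, pd.CategoricalDtype):
        dummies = pd.get_dummies(series.astype(str), drop_first=True)
        return dummies.values.astype(float)
    return series.values.astype(float)[:, None]


@dataclass
class PermanovaResults:
    """Sequential PERMANOVA partition: per-term R², pseudo-F and permutation p."""

    table: pd.DataFrame
    n_perm: int
    seed: int | None
    metric: str

    @property
    def r2(self) -> pd.Series:
        return self.table["R2"].drop(["Residual", "Total"])

    @property
    def pvalues(self) -> pd.Series:
        return self.table["p"].drop(["Residual", "Total"])

    @property
    def residual_r2(self) -> float:
        return float(self.table.loc["Residual", "R2"])

    def summary(self) -> str:
        head = f"PERMANOVA ({self.metric} distances, {self.n_perm} permutations)"
        return head + "\n" + self.table.to_string()


class Permanova:
    """Distance-matrix ANOVA with sequential (entry-order) terms.

    Parameters
    ----------
    dist
        A :class:`~calcmicro.tables.DistanceMatrix`.
    metadata
        :class:`~calcmicro.tables.SampleMetadata` or a DataFrame indexed by
        sample id providing the term columns.
    terms
        Ordered term names; categorical columns are dummy-coded, numeric
        columns enter as single covariates.
    """

    def __init__(self, dist: DistanceMatrix, metadata, terms):
        frame = metadata.frame if isinstance(metadata, SampleMetadata) else metadata
        frame = frame.loc[dist.ids]
        self.dist = dist
        self.terms = list(terms)
        n = dist.n
        self._g = _gower_center(dist.values)
        designs = [np.ones((n, 1))]
        ranks = [1]
        self._dfs = []
        x = np.ones((n, 1))
        for term in self.terms:
            if term not in frame.columns:
                raise ValueError(f"unknown term {term!r}")
            cols = _term_columns(frame[term], term)
            x = np.hstack([x, cols])
            r = np.linalg.matrix_rank(x)
            if r <= ranks[-1]:
                raise ValueError(f"rank-deficient design at term {term!r}")
            self._dfs.append(r - ranks[-1])
            ranks.append(r)
            designs.append(x.copy())
        self._hats = [_hat(x) for x in designs]
        self._n = n
        self._df_res = n - ranks[-1]
        if self._df_res <= 0:
            raise ValueError("no residual degrees of freedom")

    def _partition(self, g: np.ndarray):
        tr = [float(np.sum(h * g)) for h in self._hats]  # tr(H G) for sym H
        ss_total = float(np.trace(g))
        ss_terms = np.diff(tr)
        ss_res = ss_total - tr[-1]
        return ss_terms, ss_res, ss_total

    def _fstats(self, g: np.ndarray) -> np.ndarray:
        ss_terms, ss_res, _ = self._partition(g)
        ms_res = ss_res / self._df_res
        with np.errstate(invalid="ignore", divide="ignore"):
            return (ss_terms / np.array(self._dfs)) / ms_res

    def fit(self, n_perm: int = 999, seed: int | None = 0,
            permutations: str = "random") -> PermanovaResults:
        """Estimate R², pseudo-F and permutation p-values.

        ``permutations="exact"`` enumerates all n! row/column permutations
        (small n only) and reports ``p = #(F* >= F) / n!``; the default draws
        ``n_perm`` random permutations and reports ``(1 + #(F* >= F)) /
        (1 + n_perm)``.
        """
        g = self._g
        ss_terms, ss_res, ss_total = self._partition(g)
        degenerate = ss_total <= 1e-12
        if degenerate:
            f_obs = np.zeros(len(self.terms))
            pvals = np.ones(len(self.terms))
        else:
            f_obs = self._fstats(g)
            # tie tolerance is relative: permutations equivalent to the
            # observed layout must count as >= despite float accumulation
            tol = 1e-9 * np.maximum(1.0, np.abs(f_obs))
            if permutations == "exact":
                count = np.zeros(len(self.terms))
                total = 0
                for perm in itertools.permutations(range(self._n)):
                    gp = g[np.ix_(perm, perm)]
                    count += self._fstats(gp) >= f_obs - tol
                    total += 1
                pvals = count / total
            else:
                rng = np.random.default_rng(seed)
                count = np.zeros(len(self.terms))
                batch = 256
                done = 0
                while done < n_perm:
                    b = min(batch, n_perm - done)
                    perms = np.array([rng.permutation(self._n) for _ in range(b)])
                    gb = g[perms[:, :, None], perms[:, None, :]]
                    trs = [np.einsum("ij,bij->b", h, gb) for h in self._hats]
                    ssb = np.diff(np.array(trs), axis=0).T  # b x terms
                    ss_res_b = np.trace(gb, axis1=1, axis2=2) - trs[-1]
                    with np.errstate(invalid="ignore", divide="ignore"):
                        fb = (ssb / np.array(self._dfs)) / (
                            ss_res_b[:, None] / self._df_res
                        )
                    count += (fb >= f_obs[None, :] - tol[None, :]).sum(axis=0)
                    done += b
                pvals = (1.0 + count) / (1.0 + n_perm)

        rows = []
        for t, df, ss, f, p in zip(self.terms, self._dfs, ss_terms, f_obs, pvals):
            r2 = ss / ss_total if not degenerate else 0.0
            rows.append((t, df, ss, r2, f, p))
        rows.append(("Residual", self._df_res, ss_res,
                     ss_res / ss_total if not degenerate else 1.0, np.nan, np.nan))
        rows.append(("Total", self._n - 1, ss_total, 1.0, np.nan, np.nan))
        table = pd.DataFrame(
            rows, columns=["term", "df", "SumOfSqs", "R2", "F", "p"]
        ).set_index("term")
        return PermanovaResults(table, n_perm if permutations != "exact" else 0,
                                seed, self.dist.metric)


def _hat(x: np.ndarray) -> np.ndarray:
    q, r = np.linalg.qr(x)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    q = q[:, keep]
    return q @ q.T


def permanova(dist: DistanceMatrix, metadata, terms, n_perm: int = 999,
              seed: int | None = 0) -> PermanovaResults:
    """Convenience wrapper: ``Permanova(dist, metadata, terms).fit(...)``."""
    return Permanova(dist, metadata, terms).fit(n_perm=n_perm, seed=seed)


def pairwise_permanova(
    dist: DistanceMatrix,
    metadata,
    group: str,
    covariates=(),
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """PERMANOVA on each pair of group levels, BH-adjusted across pairs.

    Covariates enter the model before the group factor; a covariate without
    variation within a pair is dropped with a warning.  Pairs with fewer than
    three samples in total are skipped with a warning.
    """
    frame = metadata.frame if isinstance(metadata, SampleMetadata) else metadata
    frame = frame.loc[dist.ids]
    levels = [lv for lv in pd.unique(frame[group].dropna())]
    if len(levels) < 2:
        raise ValueError("pairwise PERMANOVA needs at least two groups")
    rows = []
    for i, (a, b) in enumerate(itertools.combinations(levels, 2)):
        ids = list(frame.index[frame[group].isin([a, b])])
        if len(ids) < 3:
            warnings.warn(f"pair ({a}, {b}) has fewer than 3 samples; skipped")
            continue
        sub = dist.select(ids)
        sub_frame = frame.loc[ids]
        terms = []
        for cov in covariates:
            if sub_frame[cov].nunique(dropna=False) < 2:
                warnings.warn(f"covariate {cov!r} constant within pair ({a}, {b}); dropped")
            else:
                terms.append(cov)
        terms.append(group)
        res = Permanova(sub, sub_frame, terms).fit(
            n_perm=n_perm, seed=None if seed is None else seed + i
        )
        rows.append(
            dict(group_a=a, group_b=b, n=len(ids),
                 R2=float(res.table.loc[group, "R2"]),
                 F=float(res.table.loc[group, "F"]),
                 p=float(res.table.loc[group, "p"]))
        )
    out = pd.DataFrame(rows)
    if len(out):
        out["p_adjusted"] = multipletests(out["p"].values, method="fdr_bh")[1]
    return out


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    """Classical MDS embedding; negative eigenvalues are reported, not dropped."""

    eigenvalues: np.ndarray
    coordinates: pd.DataFrame
    proportion_explained: np.ndarray


def pcoa(dist: DistanceMatrix) -> PcoaResult:
    """Principal coordinate analysis of a distance matrix."""
    b = _gower_center(dist.values)
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    pos = vals > 1e-10 * max(1.0, abs(vals).max())
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    frame = pd.DataFrame(
        coords, index=dist.ids, columns=[f"PC{i+1}" for i in range(coords.shape[1])]
    )
    denom = vals[vals > 0].sum()
    prop = np.where(vals > 0, vals, 0.0) / denom if denom > 0 else np.zeros_like(vals)
    return PcoaResult(vals, frame, prop)


# ---------------------------------------------------------------------------
# Feature filtering and generic group comparisons
# ---------------------------------------------------------------------------

def group_prevalence_filter(
    table: FeatureTable | pd.DataFrame, groups: pd.Series, min_frac: float = 0.30
) -> list:
    """Features present (count > 0) in at least ``min_frac`` of the samples of
    at least one group (inclusive boundary)."""
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    groups = pd.Series(groups).reindex(counts.columns)
    if groups.isna().any():
        raise ValueError("groups must cover all samples")
    pres = counts > 0
    keep = pd.Series(False, index=counts.index)
    for _, cols in pres.T.groupby(groups):
        keep |= cols.mean(axis=0) >= min_frac
    return list(counts.index[keep])


def group_compare(
    values, groups: pd.Series, test: str = "wilcoxon", alternative: str = "two-sided"
) -> pd.DataFrame:
    """Two-group comparison per feature with BH adjustment across features.

    ``values`` is a feature-by-sample DataFrame or a single Series; ``test`` is
    ``"wilcoxon"`` (rank-sum; exact p for small tie-free samples) or
    ``"welch_t"``.
    """
    if isinstance(values, pd.Series):
        frame = values.to_frame().T
    else:
        frame = pd.DataFrame(values)
    groups = pd.Series(groups).reindex(frame.columns)
    levels = pd.unique(groups.dropna())
    if len(levels) != 2:
        raise ValueError("group_compare requires exactly two groups")
    a_cols = groups.index[groups == levels[0]]
    b_cols = groups.index[groups == levels[1]]
    rows = []
    for feature in frame.index:
        x = frame.loc[feature, a_cols].astype(float).values
        y = frame.loc[feature, b_cols].astype(float).values
        if test == "wilcoxon":
            method = "exact" if (len(x) + len(y) <= 25
                                 and len(np.unique(np.concatenate([x, y])))
                                 == len(x) + len(y)) else "auto"
            stat, p = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
        elif test == "welch_t":
            stat, p = stats.ttest_ind(x, y, equal_var=False, alternative=alternative)
        else:
            raise ValueError(f"unknown test {test!r}")
        rows.append(dict(feature=feature, statistic=float(stat), p=float(p)))
    out = pd.DataFrame(rows).set_index("feature")
    out["p_adjusted"] = multipletests(out["p"].values, method="fdr_bh")[1]
    return out
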