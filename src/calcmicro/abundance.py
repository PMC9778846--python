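"""ANCOM-style differential abundance with structural zeros and covariates.

For every ordered pair of taxa (i, j) the additive log-ratio
``log((x_i + 1) / (x_j + 1))`` is tested against the grouping factor — by
Kruskal-Wallis when there are no covariates, otherwise by the partial F-test
of the group factor in an additive linear model that includes the covariates
(e.g. read depth).  ``W_i`` counts, after multiple-testing correction within
taxon *i*, how many of the m−1 ratio tests reject.  A taxon is called
differentially abundant when ``W`` lies strictly above the 0.9 quantile of the
W distribution AND a per-taxon Kruskal-Wallis posthoc test on CLR abundances
is significant after Bonferroni correction, or when the taxon is structurally
absent from one or more groups.

The two-pass design guards against batch artefacts: the analysis is run once
against the biological grouping (adjusting for read depth) and once against
the dataset label (adjusting for the grouping); species whose genus contains
any dataset-associated taxon are struck from the biological list
(:func:`two_pass_filter`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import FeatureTable, SampleMetadata, clr_transform


def structural_zeros(
    table: FeatureTable | pd.DataFrame, groups: pd.Series, support: float = 0.25
) -> pd.DataFrame:
    """Per-taxon, per-group structural-absence flags.

    A (taxon, group) is flagged when the taxon has zero counts in every sample
    of that group and is present in at least ``support`` of the samples of some
    other group (this support requirement prevents singleton-driven calls).
    """
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    groups = pd.Series(groups).reindex(counts.columns)
    levels = list(pd.unique(groups.dropna()))
    if len(levels) < 2:
        raise ValueError("structural zeros need at least two groups")
    prevalence = {}
    for g in levels:
        cols = groups.index[groups == g]
        if len(cols) == 0:
            raise ValueError(f"empty group {g!r}")
        prevalence[g] = (counts[cols] > 0).mean(axis=1)
    prev = pd.DataFrame(prevalence)
    flags = pd.DataFrame(False, index=counts.index, columns=levels)
    for g in levels:
        others = prev.drop(columns=g)
        flags[g] = (prev[g] == 0.0) & (others.max(axis=1) >= support)
    return flags


def _kruskal_matrix(y: np.ndarray, codes: np.ndarray, n_groups: int) -> np.ndarray:
    """Vectorised Kruskal-Wallis p-values for each column of ``y``."""
    n, p = y.shape
    ranks = stats.rankdata(y, axis=0)
    sums = np.zeros((n_groups, p))
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    for g in range(n_groups):
        sums[g] = ranks[codes == g].sum(axis=0)
    h = 12.0 / (n * (n + 1)) * (sums**2 / counts[:, None]).sum(axis=0) - 3 * (n + 1)
    # tie correction: 1 - sum(t^3 - t) / (n^3 - n) per column
    s = np.sort(y, axis=0)
    new_run = np.vstack([np.ones((1, p), dtype=bool), s[1:] != s[:-1]])
    row = np.arange(n)[:, None]
    run_start = np.maximum.accumulate(np.where(new_run, row, 0), axis=0)
    j = row - run_start + 1.0
    tie = (3 * j**2 - 3 * j + 1).sum(axis=0) - n
    denom = 1.0 - tie / (n**3 - n)
    with np.errstate(invalid="ignore", divide="ignore"):
        hc = h / denom
    pvals = stats.chi2.sf(hc, n_groups - 1)
    pvals = np.where(denom <= 0, 1.0, pvals)  # all values tied
    return pvals


def _ols_f_matrix(y: np.ndarray, x_reduced: np.ndarray, x_full: np.ndarray) -> np.ndarray:
    """Partial-F p-values of the terms added in ``x_full`` for each column."""
    n = y.shape[0]

    def proj(x):
        q, r = np.linalg.qr(x)
        keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
        return q[:, keep]

    qr_, qf = proj(x_reduced), proj(x_full)
    df_g = qf.shape[1] - qr_.shape[1]
    df_e = n - qf.shape[1]
    if df_g <= 0:
        raise ValueError("covariate collinear with the group factor")
    if df_e <= 0:
        raise ValueError("no residual degrees of freedom")
    rss_r = (y**2).sum(axis=0) - ((qr_.T @ y) ** 2).sum(axis=0)
    rss_f = (y**2).sum(axis=0) - ((qf.T @ y) ** 2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        f = ((rss_r - rss_f) / df_g) / (rss_f / df_e)
    pvals = stats.f.sf(f, df_g, df_e)
    return np.where(rss_f <= 1e-12 * np.maximum(rss_r, 1e-300), np.where(rss_r > 1e-12, 0.0, 1.0), pvals)


@dataclass
class AncomResults:
    """Per-taxon differential-abundance calls.

    ``frame`` columns: ``W``, ``W_rank`` (quantile rank of W among taxa),
    ``sz_<group>`` structural-zero flags, ``kw_p`` / ``kw_p_bonf`` posthoc
    p-values, ``detected`` and ``pass_label``.
    """

    frame: pd.DataFrame
    w_cutoff: float
    group: str
    pass_label: str | None = None

    @property
    def detected(self) -> list:
        return list(self.frame.index[self.frame["detected"]])

    @property
    def w(self) -> pd.Series:
        return self.frame["W"]

    def summary(self) -> str:
        n_det = int(self.frame["detected"].sum())
        head = (f"ANCOM vs {self.group!r}: {n_det} of {len(self.frame)} taxa detected "
                f"(W cutoff {self.w_cutoff:.1f})")
        cols = [c for c in self.frame.columns if c != "pass_label"]
        return head + "\n" + self.frame.loc[self.frame["detected"], cols].to_string()


class Ancom:
    """ANCOM differential-abundance model for a count table.

    Parameters
    ----------
    table
        :class:`~calcmicro.tables.FeatureTable` or a taxon-by-sample count
        DataFrame (m >= 3 taxa).
    metadata
        :class:`~calcmicro.tables.SampleMetadata` or DataFrame indexed by
        sample id.
    group
        Metadata column with >= 2 levels.
    covariates
        Metadata columns adjusted for in each ratio test (additive model).
    """

    def __init__(self, table, metadata, group: str, covariates=()):
        counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
        frame = metadata.frame if isinstance(metadata, SampleMetadata) else metadata
        frame = frame.loc[counts.columns]
        if counts.shape[0] < 3:
            raise ValueError("ANCOM requires at least three taxa")
        self.counts = counts
        self.groups = frame[group]
        if self.groups.nunique() < 2:
            raise ValueError("group factor must have at least two levels")
        self.group = group
        self.covariates = list(covariates)
        self._frame = frame

    def fit(
        self,
        alpha: float = 0.05,
        w_quantile: float = 0.9,
        correction: str = "fdr_bh",
        sz_support: float = 0.25,
        require_posthoc: bool = True,
        quantile_over_positive: bool = True,
    ) -> AncomResults:
        counts = self.counts
        m, n = counts.shape
        levels = list(pd.unique(self.groups))
        codes = pd.Categorical(self.groups, categories=levels).codes.astype(int)

        logc = np.log(counts.values.astype(float) + 1.0)
        pairs = [(i, j) for i in range(m) for j in range(i + 1, m)]
        y = np.empty((n, len(pairs)))
        for k, (i, j) in enumerate(pairs):
            y[:, k] = logc[i] - logc[j]

        if self.covariates:
            x_r = np.hstack(
                [np.ones((n, 1))]
                + [self._covariate_columns(c) for c in self.covariates]
            )
            dummies = pd.get_dummies(pd.Series(codes), drop_first=True).values.astype(float)
            x_f = np.hstack([x_r, dummies])
            pair_p = _ols_f_matrix(y, x_r, x_f)
        else:
            pair_p = _kruskal_matrix(y, codes, len(levels))

        pmat = np.full((m, m), np.nan)
        for k, (i, j) in enumerate(pairs):
            pmat[i, j] = pmat[j, i] = pair_p[k]
        w = np.zeros(m, dtype=int)
        for i in range(m):
            pv = np.delete(pmat[i], i)
            ok = ~np.isnan(pv)
            if ok.any():
                rej = multipletests(pv[ok], alpha=alpha, method=correction)[0]
                w[i] = int(rej.sum())

        w_series = pd.Series(w, index=counts.index, name="W")
        pool = w_series[w_series > 0] if quantile_over_positive else w_series
        cutoff = float(pool.quantile(0.9)) if len(pool) else np.inf
        detected_w = w_series > cutoff

        sz = structural_zeros(counts, self.groups, support=sz_support)
        sz_any = sz.any(axis=1)

        clr = clr_transform(counts)
        kw_p = np.ones(m)
        for i in range(m):
            vals = [clr.iloc[i][codes == g].values for g in range(len(levels))]
            if np.ptp(clr.iloc[i].values) < 1e-12:
                kw_p[i] = 1.0  # constant across all samples
            else:
                kw_p[i] = stats.kruskal(*vals).pvalue
        kw_bonf = np.minimum(kw_p * m, 1.0)

        if require_posthoc:
            detected = (detected_w & (kw_bonf < alpha)) | sz_any
        else:
            detected = detected_w | sz_any

        frame = pd.DataFrame(index=counts.index)
        frame["W"] = w_series
        frame["W_rank"] = w_series.rank(pct=True)
        for g in sz.columns:
            frame[f"sz_{g}"] = sz[g]
        frame["structural_zero"] = sz_any
        frame["kw_p"] = kw_p
        frame["kw_p_bonf"] = kw_bonf
        frame["detected"] = detected
        return AncomResults(frame, cutoff, self.group)

    def _covariate_columns(self, name: str) -> np.ndarray:
        col = self._frame[name]
        if col.isna().any():
            raise ValueError(f"covariate {name!r} has missing values")
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            return pd.get_dummies(col.astype(str), drop_first=True).values.astype(float)
        v = col.values.astype(float)[:, None]
        return v - v.mean()


def ancom_w(table, metadata, group: str, covariates=(), **fit_kwargs) -> AncomResults:
    """Convenience wrapper: ``Ancom(table, metadata, group, covariates).fit()``."""
    return Ancom(table, metadata, group, covariates).fit(**fit_kwargs)


def two_pass_filter(
    subspecies_result: AncomResults,
    dataset_result: AncomResults,
    taxonomy: pd.DataFrame,
) -> list:
    """Final differential-abundance set after the dataset artefact pass.

    Keeps subspecies-detected taxa that resolve to genus or species rank,
    minus every species whose genus contains any dataset-detected taxon.
    Taxa without a genus are excluded with a warning.
    """
    genus = taxonomy["genus"]
    rank = taxonomy.get("rank", pd.Series("species", index=taxonomy.index))

    def usable(t) -> bool:
        if rank.get(t) not in ("genus", "species") or pd.isna(genus.get(t)):
            warnings.warn(f"taxon {t!r} lacks genus/species rank; excluded")
            return False
        return True

    sub = [t for t in subspecies_result.detected if usable(t)]
    bad_genera = {genus.get(t) for t in dataset_result.detected if genus.get(t) is not None}
    return [t for t in sub if genus.get(t) not in bad_genera]


def marker_taxa(
    table,
    metadata,
    group_col: str,
    group_a: str,
    group_b: str,
    covariates=(),
    **fit_kwargs,
) -> list:
    """Taxa differentially abundant between two specific groups (ANCOM on the
    two-group restriction), e.g. mountain vs western lowland."""
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    frame = metadata.frame if isinstance(metadata, SampleMetadata) else metadata
    frame = frame.loc[counts.columns]
    keep = frame.index[frame[group_col].isin([group_a, group_b])]
    if frame.loc[keep, group_col].nunique() < 2:
        raise ValueError("both groups must be present")
    sub_counts = counts[keep]
    res = Ancom(sub_counts, frame.loc[keep], group_col, covariates).fit(**fit_kwargs)
    return res.detected
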