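"""Altitude-stratified inference, Mantel/MRM distance regression and dietary
filtering.

Altitude is the ecological proxy: Grauer's gorilla samples are split into low
(<= 1000 masl) and high (> 1000 masl) altitude bands while the other
subspecies keep their own labels, giving the four groups used in the
stratified pairwise PERMANOVA over marker taxa.  Ecological distances are
Euclidean on altitude (|Δ masl|) and on museum-record coordinates, with a
log(d + 1) variant of the geographic distances used as the controlled matrix
in partial Mantel tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .tables import (DistanceMatrix, FeatureTable, SampleMetadata,
                     aitchison_distances, jaccard_distances)
from .community import Permanova

BAND_GROUPS = ["western_lowland", "grauers_low", "grauers_high", "mountain"]
TABLE3_PAIRS = [
    ("mountain", "grauers_low"),
    ("mountain", "grauers_high"),
    ("western_lowland", "grauers_low"),
    ("western_lowland", "grauers_high"),
    ("grauers_low", "grauers_high"),
]


def altitude_band(meta: SampleMetadata | pd.DataFrame, cutoff: float = 1000.0) -> pd.Series:
    """Group labels with Grauer's samples split at the altitude cutoff.

    Grauer's samples are labelled ``grauers_low`` when altitude <= cutoff and
    ``grauers_high`` otherwise; other subspecies keep their subspecies label.
    """
    frame = meta.frame if isinstance(meta, SampleMetadata) else meta
    out = {}
    for sid, row in frame.iterrows():
        sub = row.get("subspecies")
        if sub == "grauers":
            alt = row.get("altitude")
            if pd.isna(alt):
                raise ValueError(f"Grauer's sample {sid!r} lacks altitude")
            out[sid] = "grauers_low" if alt <= cutoff else "grauers_high"
        else:
            out[sid] = sub
    return pd.Series(out, name="band_group")


@dataclass
class EcoDistances:
    """Altitude and geographic distance matrices over one sample set."""

    altitude: DistanceMatrix
    geographic: DistanceMatrix
    geographic_log: DistanceMatrix


def eco_distances(meta: SampleMetadata | pd.DataFrame) -> EcoDistances:
    """Euclidean altitude and coordinate distances from museum records.

    Geographic distances are Euclidean on raw (latitude, longitude) degrees;
    the log variant is ``log(d + 1)`` so that zero distances stay finite.
    """
    frame = meta.frame if isinstance(meta, SampleMetadata) else meta
    for col in ("altitude", "latitude", "longitude"):
        if col not in frame.columns or frame[col].isna().any():
            raise ValueError(f"missing {col} for ecological distances")
    ids = list(frame.index)
    alt = frame["altitude"].values.astype(float)
    d_alt = np.abs(alt[:, None] - alt[None, :])
    xy = frame[["latitude", "longitude"]].values.astype(float)
    d_geo = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=2))
    return EcoDistances(
        DistanceMatrix(ids, d_alt, "euclidean"),
        DistanceMatrix(ids, d_geo, "euclidean"),
        DistanceMatrix(ids, np.log(d_geo + 1.0), "euclidean"),
    )


# ---------------------------------------------------------------------------
# Mantel statistics
# ---------------------------------------------------------------------------

@dataclass
class MantelResult:
    """(Partial) Mantel correlation with a one-sided permutation p-value."""

    r: float
    p: float
    n_perm: int
    seed: int | None
    method: str
    controlled: bool

    def summary(self) -> str:
        kind = "Partial Mantel" if self.controlled else "Mantel"
        return (f"{kind} ({self.method}): r = {self.r:.4f}, "
                f"p = {self.p:.4g} ({self.n_perm} permutations)")


def _unfold(values: np.ndarray) -> np.ndarray:
    iu = np.triu_indices(values.shape[0], 1)
    return values[iu]


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa <= 1e-300 or sb <= 1e-300:
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _check_conformable(*mats: DistanceMatrix) -> None:
    ids = mats[0].ids
    for m in mats[1:]:
        if list(m.ids) != list(ids):
            raise ValueError("distance matrices must share the same sample ids")


def mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 10_000,
    seed: int | None = 0,
    permutations: str = "random",
) -> MantelResult:
    """Simple Mantel test (one-sided, greater) by row/column permutation of A."""
    return _mantel_impl(a, b, None, method, n_perm, seed, permutations)


def partial_mantel(
    a: DistanceMatrix,
    b: DistanceMatrix,
    c: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 10_000,
    seed: int | None = 0,
    permutations: str = "random",
) -> MantelResult:
    """Partial Mantel correlation of A and B controlling for C.

    ``r_AB.C = (r_AB - r_AC r_BC) / sqrt((1 - r_AC^2)(1 - r_BC^2))`` on the
    unfolded upper triangles (rank-transformed first for ``spearman``); the
    p-value permutes rows/columns of A jointly.  A constant C reduces the
    statistic to the simple Mantel r exactly.
    """
    return _mantel_impl(a, b, c, method, n_perm, seed, permutations)


def _partial_r(av, bv, cv) -> float:
    r_ab = _corr(av, bv)
    if cv is None:
        return r_ab
    r_ac, r_bc = _corr(av, cv), _corr(bv, cv)
    if abs(r_ac) >= 1.0 - 1e-12 or abs(r_bc) >= 1.0 - 1e-12:
        raise ValueError("controlled matrix is perfectly correlated; partial r degenerate")
    if abs(r_ac) < 1e-300 and abs(r_bc) < 1e-300:
        return r_ab
    return (r_ab - r_ac * r_bc) / np.sqrt((1 - r_ac**2) * (1 - r_bc**2))


def _mantel_impl(a, b, c, method, n_perm, seed, permutations) -> MantelResult:
    mats = (a, b) if c is None else (a, b, c)
    _check_conformable(*mats)
    n = a.n
    iu = np.triu_indices(n, 1)

    def unfold_ranked(m):
        v = m.values[iu]
        return stats.rankdata(v) if method == "spearman" else v

    bv = unfold_ranked(b)
    cv = unfold_ranked(c) if c is not None else None
    av = unfold_ranked(a)
    r_obs = _partial_r(av, bv, cv)

    def stat_for(perm) -> float:
        ap = a.values[np.ix_(perm, perm)][iu]
        if method == "spearman":
            ap = stats.rankdata(ap)
        return _partial_r(ap, bv, cv)

    if permutations == "exact":
        rs = [stat_for(p) for p in itertools.permutations(range(n))]
        p = float(np.mean(np.array(rs) >= r_obs - 1e-9))
        return MantelResult(float(r_obs), p, len(rs), seed, method, c is not None)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        if stat_for(rng.permutation(n)) >= r_obs - 1e-9:
            count += 1
    p = (1.0 + count) / (1.0 + n_perm)
    return MantelResult(float(r_obs), p, n_perm, seed, method, c is not None)


# ---------------------------------------------------------------------------
# Multiple regression on distance matrices (single predictor)
# ---------------------------------------------------------------------------

@dataclass
class MrmResults:
    """OLS of one unfolded distance matrix on another with permutation p."""

    r2: float
    intercept: float
    coefficient: float
    p: float
    n_perm: int
    seed: int | None

    def summary(self) -> str:
        return (f"MRM: R^2 = {self.r2:.4f}, slope = {self.coefficient:.4f}, "
                f"p = {self.p:.4g} ({self.n_perm} permutations)")


class Mrm:
    """Regression of dependent distances A on predictor distances B."""

    def __init__(self, a: DistanceMatrix, b: DistanceMatrix):
        _check_conformable(a, b)
        self.a, self.b = a, b

    def fit(self, n_perm: int = 1000, seed: int | None = 0) -> MrmResults:
        n = self.a.n
        iu = np.triu_indices(n, 1)
        bv = self.b.values[iu]
        av = self.a.values[iu]
        slope, intercept, r2 = _ols_1d(av, bv)
        rng = np.random.default_rng(seed)
        count = 0
        for _ in range(n_perm):
            perm = rng.permutation(n)
            ap = self.a.values[np.ix_(perm, perm)][iu]
            _, _, r2p = _ols_1d(ap, bv)
            if r2p >= r2 - 1e-9:
                count += 1
        p = (1.0 + count) / (1.0 + n_perm)
        return MrmResults(float(r2), float(intercept), float(slope), p, n_perm, seed)


def _ols_1d(y: np.ndarray, x: np.ndarray):
    vx = x.var()
    if vx <= 1e-300:
        return 0.0, float(y.mean()), 0.0
    slope = np.cov(x, y, bias=True)[0, 1] / vx
    intercept = y.mean() - slope * x.mean()
    resid = y - intercept - slope * x
    tss = ((y - y.mean()) ** 2).sum()
    r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
    return slope, intercept, r2


def mrm(a: DistanceMatrix, b: DistanceMatrix, n_perm: int = 1000,
        seed: int | None = 0) -> MrmResults:
    """Convenience wrapper: ``Mrm(a, b).fit(...)``."""
    return Mrm(a, b).fit(n_perm=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# Altitude-stratified pairwise contrasts over marker taxa
# ---------------------------------------------------------------------------

def stratified_contrasts(
    table: FeatureTable,
    meta: SampleMetadata,
    markers,
    covariates=("dataset",),
    cutoff: float = 1000.0,
    n_perm: int = 999,
    seed: int | None = 0,
) -> pd.DataFrame:
    """Pairwise PERMANOVA of the four altitude-band groups over marker taxa.

    The five contrasts (mountain and western lowland against each Grauer's
    altitude band, plus the two Grauer's bands against each other) are tested
    on Jaccard and Aitchison distances computed over the marker taxa only, the
    dataset covariate entering each model first; p-values are BH-adjusted
    within each metric.
    """
    markers = [t for t in markers if t in set(table.taxa)]
    if not markers:
        raise ValueError("empty marker-taxon set")
    frame = meta.frame
    bands = altitude_band(meta.select(meta.calculus_samples()), cutoff=cutoff)
    samples = [s for s in bands.index if bands[s] in BAND_GROUPS and s in set(table.samples)]
    missing = [g for g in BAND_GROUPS if g not in set(bands[samples])]
    if missing:
        raise ValueError(f"band group(s) not populated: {missing}")
    sub = table.select_taxa(markers).select_samples(samples)
    work = frame.loc[samples].copy()
    work["band_group"] = bands[samples]
    dists = {
        "jaccard": jaccard_distances(sub),
        # structural absences can empty a sample on a small marker panel
        "aitchison": aitchison_distances(sub, allow_empty=True),
    }
    rows = []
    import warnings as _warnings

    for metric, dist in dists.items():
        for i, (ga, gb) in enumerate(TABLE3_PAIRS):
            ids = list(work.index[work["band_group"].isin([ga, gb])])
            d = dist.select(ids)
            w = work.loc[ids]
            terms = []
            for cov in covariates:
                if w[cov].nunique(dropna=False) >= 2:
                    terms.append(cov)
                else:
                    _warnings.warn(f"covariate {cov!r} constant in pair ({ga}, {gb}); dropped")
            terms.append("band_group")
            res = Permanova(d, w, terms).fit(
                n_perm=n_perm, seed=None if seed is None else seed + i
            )
            rows.append(
                dict(metric=metric, group_a=ga, group_b=gb, n=len(ids),
                     R2=float(res.table.loc["band_group", "R2"]),
                     p=float(res.table.loc["band_group", "p"]))
            )
    out = pd.DataFrame(rows)
    out["p_adjusted"] = np.nan
    for metric in dists:
        mask = out["metric"] == metric
        out.loc[mask, "p_adjusted"] = multipletests(
            out.loc[mask, "p"].values, method="fdr_bh"
        )[1]
    return out


# ---------------------------------------------------------------------------
# Dietary filtering
# ---------------------------------------------------------------------------

def diet_filter(
    table: FeatureTable,
    meta: SampleMetadata,
    reference: pd.DataFrame,
    min_reads: int = 10,
) -> FeatureTable:
    """Dietary-genus filtering: museum-control removal, low-count zeroing and
    restriction to known food families.

    Genera present in any museum control are removed everywhere; cells with
    fewer than ``min_reads`` reads are zeroed; the retained genera are those
    whose family appears in the reference food list (family-level inclusion:
    a genus not itself listed is kept when its family is).  The result is
    restricted to calculus samples.
    """
    controls = [s for s in meta.museum_controls() if s in set(table.samples)]
    in_controls = (
        set(table.taxa[(table.counts[controls] > 0).any(axis=1)]) if controls else set()
    )
    work = table.drop_taxa(in_controls)
    counts = work.counts.where(work.counts >= min_reads, 0)
    work = FeatureTable(counts, work.taxonomy, work.flags)
    families = set(reference["family"].dropna())
    keep = [t for t in work.taxa if work.taxonomy.loc[t, "family"] in families]
    work = work.select_taxa(keep)
    calculus = [s for s in meta.calculus_samples() if s in set(work.samples)]
    return work.select_samples(calculus).drop_empty_taxa()
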