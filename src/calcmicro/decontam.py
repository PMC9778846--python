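"""Sample-level QC gates and the multi-step taxon decontamination procedure.

The pipeline applied to historical dental-calculus profiles is, in order:

1. **Read-count gate** — calculus samples with fewer than 300,000 processed
   reads are excluded (strict "less than"); blanks and museum controls are
   never removed by this gate.
2. **Oral-proportion gate** — samples whose cumulative oral source proportion
   is lower than 3% are excluded.  Source proportions may come from an external
   source-tracking tool or from :func:`estimate_source_proportions_nnls`.
3. **Prevalence scoring** — per dataset, each taxon receives a one-sided exact
   (hypergeometric/Fisher) probability that its prevalence in blanks is at most
   its prevalence in samples; a small score means blank-enriched.  Taxa scoring
   below the dataset threshold (0.2 for the newly generated dataset, 0.3 for
   the published one) are called contaminants and removed from the *full*
   dataset regardless of which subset flagged them.
4. **Abundance zeroing** — cells with relative abundance < 0.005% within their
   sample are set to zero (totals computed before zeroing).
5. **Museum-control exceedance** — a taxon is removed when its maximum relative
   abundance over the museum controls is strictly higher than its maximum over
   the calculus samples.
6. **Contaminant-list removal with oral rescue** — species of genera on the
   common-contaminant lists are removed unless the genus is in an oral database
   and the species is damage-authentic, or has too few reads to be tested
   (untestable taxa are automatically retained).

:func:`decontaminate` runs steps 3-6 and returns the filtered table restricted
to calculus samples together with a :class:`DecontamReport` naming, for every
removed taxon, the step that removed it.  Because the controls are consumed,
re-running the pipeline on its own output is a no-op (idempotence).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.stats import hypergeom

from .tables import FeatureTable, SampleMetadata

DEFAULT_PREVALENCE_THRESHOLDS = {"new": 0.2, "published": 0.3}


# ---------------------------------------------------------------------------
# Sample-level QC
# ---------------------------------------------------------------------------

def filter_low_read_samples(meta: SampleMetadata, min_reads: int = 300_000) -> pd.Index:
    """Retained sample ids after the read-count gate.

    Calculus samples with ``read_count < min_reads`` are excluded; blanks and
    museum controls are exempt.  Missing read counts raise an error naming the
    sample.
    """
    frame = meta.frame
    if "read_count" not in frame.columns or frame["read_count"].isna().any():
        missing = (
            list(frame.index[frame["read_count"].isna()])
            if "read_count" in frame.columns
            else list(frame.index)
        )
        raise ValueError(f"missing read count for sample(s): {missing}")
    is_calculus = frame["role"] == "calculus"
    drop = is_calculus & (frame["read_count"] < min_reads)
    return frame.index[~drop]


def filter_low_oral_samples(
    proportions: pd.DataFrame, threshold: float = 0.03, oral_columns=("oral",)
) -> pd.Index:
    """Retained sample ids after the oral-proportion gate (strict ``< threshold``
    exclusion).  ``proportions`` rows must lie on the simplex (sum to 1)."""
    sums = proportions.sum(axis=1)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = list(sums.index[~np.isclose(sums, 1.0, atol=1e-6)])
        raise ValueError(f"source proportions do not sum to 1 for: {bad}")
    oral = proportions[list(oral_columns)].sum(axis=1)
    return proportions.index[oral >= threshold]


def estimate_source_proportions_nnls(
    table: FeatureTable | pd.DataFrame, references: pd.DataFrame
) -> pd.DataFrame:
    """Least-squares mixture proportions of reference source profiles.

    A simple stand-in for EM-based source tracking: each sample's relative
    abundance vector is regressed (nonnegatively) on the reference mean
    profiles over the shared taxon space; unexplained mass is reported as
    ``unknown`` and the weights are renormalised onto the simplex.
    """
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    shared = counts.index.intersection(references.index)
    if len(shared) == 0:
        raise ValueError("no taxa shared between table and reference profiles")
    refs = references.loc[shared]
    refs = refs / refs.sum(axis=0).replace(0, np.nan)
    refs = refs.fillna(0.0)
    rel = counts.loc[shared] / counts.sum(axis=0).replace(0, np.nan)
    rel = rel.fillna(0.0)
    out = {}
    A = refs.values
    for sample in counts.columns:
        b = rel[sample].values
        w, _ = nnls(A, b)
        total = w.sum()
        unknown = max(0.0, 1.0 - total)
        vec = np.concatenate([w, [unknown]])
        s = vec.sum()
        out[sample] = vec / s if s > 0 else np.append(np.zeros(len(w)), 1.0)
    return pd.DataFrame(out, index=list(refs.columns) + ["unknown"]).T


# ---------------------------------------------------------------------------
# Taxon decontamination
# ---------------------------------------------------------------------------

def prevalence_contaminant_score(
    table: FeatureTable | pd.DataFrame,
    blank_samples,
    calculus_samples,
) -> pd.Series:
    """One-sided exact blank-enrichment score per taxon.

    With ``b`` of ``nb`` blanks and ``s`` of ``ns`` samples positive, the score
    is ``P(X >= b)`` for ``X ~ Hypergeometric(N=nb+ns, K=b+s, n=nb)`` — the
    probability of seeing at least the observed blank prevalence if presence
    were independent of the blank/sample split.  Small scores mean
    blank-enriched.
    """
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    blanks = list(blank_samples)
    samples = list(calculus_samples)
    if not blanks or not samples:
        raise ValueError("prevalence scoring needs at least one blank and one sample")
    b = (counts[blanks] > 0).sum(axis=1).values
    s = (counts[samples] > 0).sum(axis=1).values
    nb, ns = len(blanks), len(samples)
    score = hypergeom.sf(b - 1, nb + ns, b + s, nb)
    return pd.Series(np.clip(score, 0.0, 1.0), index=counts.index)


def prevalence_contaminants(
    table: FeatureTable,
    meta: SampleMetadata,
    thresholds: dict[str, float] | None = None,
) -> tuple[set, pd.DataFrame]:
    """Per-dataset prevalence calls, unioned over datasets.

    Returns ``(contaminant taxa, score frame)`` where the frame has one score
    column per dataset.  Datasets without blanks are skipped with a warning.
    Blanks (extraction + library) are pooled as the control class; museum
    controls are not used here.
    """
    thresholds = dict(DEFAULT_PREVALENCE_THRESHOLDS if thresholds is None else thresholds)
    frame = meta.frame.loc[meta.frame.index.intersection(table.samples)]
    contaminants: set = set()
    scores = {}
    datasets = [d for d in frame["dataset"].dropna().unique()]
    for ds in datasets:
        in_ds = frame["dataset"] == ds
        blanks = frame.index[in_ds & frame["role"].isin({"extraction_blank", "library_blank"})]
        samples = frame.index[in_ds & (frame["role"] == "calculus")]
        if len(blanks) == 0 or len(samples) == 0:
            warnings.warn(f"dataset {ds!r} has no blanks or no samples; skipped")
            continue
        score = prevalence_contaminant_score(table, blanks, samples)
        scores[ds] = score
        thr = thresholds.get(ds, 0.2)
        contaminants |= set(score.index[score < thr])
    return contaminants, pd.DataFrame(scores)


def abundance_zero_filter(
    table: FeatureTable, min_rel: float = 5e-5
) -> FeatureTable:
    """Zero cells whose within-sample relative abundance is strictly below
    ``min_rel`` (default 0.005%); totals are computed before zeroing."""
    counts = table.counts
    totals = counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        rel = counts / totals.replace(0, np.nan)
    zeroed = counts.where(~(rel < min_rel), 0)
    return FeatureTable(zeroed.fillna(0).astype(np.int64), table.taxonomy, table.flags)


def museum_exceedance_filter(
    table: FeatureTable, meta: SampleMetadata
) -> set:
    """Taxa whose maximum relative abundance over the museum controls is
    strictly higher than over the calculus samples."""
    controls = [s for s in meta.museum_controls() if s in table.samples]
    if not controls:
        warnings.warn("no museum controls present; exceedance filter is a no-op")
        return set()
    calculus = [s for s in meta.calculus_samples() if s in table.samples]
    rel = table.relative_abundance()
    ctrl_max = rel[controls].max(axis=1)
    samp_max = rel[calculus].max(axis=1) if calculus else pd.Series(0.0, index=rel.index)
    return set(rel.index[ctrl_max > samp_max])


def contaminant_list_filter(
    table: FeatureTable,
    contaminant_genera,
    oral_genera,
    damage_calls: dict | None = None,
) -> tuple[set, dict]:
    """Removal of species from listed contaminant genera, with oral rescue.

    A species of a listed genus is removed unless its genus is also in an oral
    database AND the species is damage-authentic or untestable (too few reads).
    ``damage_calls`` maps taxon -> call, where a call is an
    :class:`~calcmicro.damage.AuthenticationCall` or one of the strings
    ``authentic``/``not_authentic``/``untestable``; missing taxa are untestable.

    Returns ``(removed taxa, rescue reasons for retained listed taxa)``.
    """
    contaminant_genera = set(contaminant_genera)
    oral_genera = set(oral_genera)
    damage_calls = damage_calls or {}
    removed: set = set()
    rescued: dict = {}
    genus = table.taxonomy["genus"]
    for taxon in table.taxa:
        g = genus.get(taxon)
        if g not in contaminant_genera:
            continue
        if g not in oral_genera:
            removed.add(taxon)
            continue
        call = damage_calls.get(taxon, "untestable")
        call = getattr(call, "call", call)
        if call == "authentic":
            rescued[taxon] = "damage_authentic"
        elif call == "untestable":
            rescued[taxon] = "untestable_retained"
        else:
            removed.add(taxon)
    return removed, rescued


@dataclass
class DecontamReport:
    """Record of the decontamination run: per-taxon scores, calls and the step
    responsible for each removal; per-sample QC outcomes."""

    scores: pd.DataFrame
    removals: pd.Series  # taxon -> step in {prevalence, abundance_zeroed,
    #                       museum_exceedance, contaminant_list}
    rescues: dict
    sample_qc: pd.DataFrame = field(default_factory=pd.DataFrame)

    def removed_by(self, step: str) -> set:
        return set(self.removals.index[self.removals == step])

    def summary(self) -> pd.DataFrame:
        out = self.removals.value_counts().rename_axis("step").to_frame("taxa_removed")
        return out


def decontaminate(
    table: FeatureTable,
    meta: SampleMetadata,
    thresholds: dict[str, float] | None = None,
    min_rel: float = 5e-5,
    contaminant_genera=(),
    oral_genera=(),
    damage_calls: dict | None = None,
    drop_empty: bool = True,
) -> tuple[FeatureTable, DecontamReport]:
    """Run the four taxon-decontamination steps in order and consume controls.

    Returns the filtered table restricted to calculus samples plus a
    :class:`DecontamReport`.  Taxa fully zeroed by the abundance filter are
    recorded under ``abundance_zeroed``.
    """
    meta_sub = meta.select([s for s in meta.samples if s in set(table.samples)])
    removals: dict[str, str] = {}

    # 1. prevalence scoring per dataset, unioned
    prev_taxa, scores = prevalence_contaminants(table, meta_sub, thresholds)
    for t in prev_taxa:
        removals[t] = "prevalence"
    work = table.drop_taxa(prev_taxa)

    # 2. per-cell abundance zeroing
    work = abundance_zero_filter(work, min_rel=min_rel)
    emptied = set(work.taxa[work.counts.sum(axis=1) == 0])
    for t in emptied:
        removals[t] = "abundance_zeroed"
    work = work.drop_taxa(emptied)

    # 3. museum-control exceedance
    exceed = museum_exceedance_filter(work, meta_sub)
    for t in exceed:
        removals[t] = "museum_exceedance"
    work = work.drop_taxa(exceed)

    # 4. contaminant-list removal with oral rescue
    listed, rescued = contaminant_list_filter(
        work, contaminant_genera, oral_genera, damage_calls
    )
    for t in listed:
        removals[t] = "contaminant_list"
    work = work.drop_taxa(listed)

    calculus = [s for s in meta_sub.calculus_samples() if s in work.samples]
    work = work.select_samples(calculus)
    if drop_empty:
        work = work.drop_empty_taxa()
    report = DecontamReport(
        scores=scores,
        removals=pd.Series(removals, dtype=object),
        rescues=rescued,
    )
    return work, report


# ---------------------------------------------------------------------------
# Sequence-level partition
# ---------------------------------------------------------------------------

_PARTITION_LABELS = {"contaminant", "noncontaminant", "unmapped"}


def partition_reads_by_reference(assignments) -> tuple[list, dict]:
    """Partition reads by best-hit label, keeping unmapped and
    noncontaminant-primary reads.

    ``assignments`` is a mapping ``read -> label`` or an iterable of
    ``(read, label)`` with labels in ``{contaminant, noncontaminant,
    unmapped}``.  Returns ``(kept read ids, counts per label)``.
    """
    items = assignments.items() if hasattr(assignments, "items") else assignments
    kept = []
    counts = {label: 0 for label in _PARTITION_LABELS}
    for read, label in items:
        if label not in _PARTITION_LABELS:
            raise ValueError(f"unknown read label {label!r} for read {read!r}")
        counts[label] += 1
        if label != "contaminant":
            kept.append(read)
    return kept, counts
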