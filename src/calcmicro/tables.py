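"""Taxonomic profile containers, report IO, compositional transforms and distances.

The central object is :class:`FeatureTable`, a taxon-by-sample count matrix with
taxonomic lineages and per-taxon annotation flags (oral-database membership,
core-hominid membership, contaminant-list membership).  Sample covariates live in
:class:`SampleMetadata` and pairwise dissimilarities in :class:`DistanceMatrix`.

Compositional analyses use the centred log-ratio (CLR) transform
``clr(x)_i = log(x_i / g(x))`` with ``g`` the geometric mean, after multiplicative
zero replacement; the Aitchison distance is the Euclidean distance between CLR
vectors and the Jaccard distance operates on presence/absence.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

RANKS = ["kingdom", "phylum", "class", "order", "family", "genus", "species"]

VALID_ROLES = {"calculus", "extraction_blank", "library_blank", "museum_control"}
CONTROL_ROLES = {"extraction_blank", "library_blank", "museum_control"}
BLANK_ROLES = {"extraction_blank", "library_blank"}


class FeatureTable:
    """Taxon-by-sample count matrix with lineage and annotation flags.

    Parameters
    ----------
    counts
        DataFrame of nonnegative integer counts, taxa as rows, samples as
        columns.  Row and column labels must be unique.
    taxonomy
        Optional DataFrame indexed by taxon with columns from
        ``["kingdom", ..., "species", "rank"]``.  When omitted a minimal
        taxonomy is inferred: rank ``species`` and genus = first whitespace
        token of the taxon name.
    flags
        Optional boolean DataFrame indexed by taxon with columns such as
        ``oral_db``, ``core_hominid``, ``contaminant_list``.
    """

    def __init__(
        self,
        counts: pd.DataFrame,
        taxonomy: pd.DataFrame | None = None,
        flags: pd.DataFrame | None = None,
    ):
        counts = pd.DataFrame(counts)
        if counts.index.has_duplicates:
            raise ValueError("duplicate taxon identifiers in feature table")
        if counts.columns.has_duplicates:
            raise ValueError("duplicate sample identifiers in feature table")
        if (counts.values < 0).any():
            raise ValueError("negative counts in feature table")
        self.counts = counts.astype(np.int64)
        if taxonomy is None:
            taxonomy = infer_taxonomy(self.counts.index)
        else:
            taxonomy = taxonomy.reindex(self.counts.index)
            if "rank" not in taxonomy.columns:
                taxonomy["rank"] = "species"
            if taxonomy["rank"].isna().any():
                raise ValueError("every taxon must have a rank")
        self.taxonomy = taxonomy
        if flags is None:
            flags = pd.DataFrame(index=self.counts.index)
        self.flags = flags.reindex(self.counts.index).fillna(False).astype(bool)

    # -- basic geometry -------------------------------------------------
    @property
    def taxa(self) -> pd.Index:
        return self.counts.index

    @property
    def samples(self) -> pd.Index:
        return self.counts.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.counts.copy(), self.taxonomy.copy(), self.flags.copy())

    def select_samples(self, samples) -> "FeatureTable":
        return FeatureTable(self.counts.loc[:, list(samples)], self.taxonomy, self.flags)

    def select_taxa(self, taxa) -> "FeatureTable":
        taxa = list(taxa)
        return FeatureTable(
            self.counts.loc[taxa], self.taxonomy.loc[taxa], self.flags.loc[taxa]
        )

    def drop_taxa(self, taxa) -> "FeatureTable":
        keep = self.taxa.difference(pd.Index(taxa), sort=False)
        return self.select_taxa(keep)

    def drop_empty_taxa(self) -> "FeatureTable":
        keep = self.counts.index[self.counts.sum(axis=1) > 0]
        return self.select_taxa(keep)

    # -- derived views ---------------------------------------------------
    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample relative abundances; all-zero samples yield zeros."""
        totals = self.counts.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            rel = self.counts / totals.replace(0, np.nan)
        return rel.fillna(0.0)

    def presence(self) -> pd.DataFrame:
        return self.counts > 0

    def genus_of(self) -> pd.Series:
        return self.taxonomy["genus"]

    def aggregate_genus(self) -> "FeatureTable":
        """Sum species counts within each genus (taxa without genus dropped)."""
        genus = self.taxonomy["genus"]
        keep = genus.notna()
        agg = self.counts.loc[keep].groupby(genus[keep]).sum()
        tax = pd.DataFrame(index=agg.index)
        tax["genus"] = agg.index
        fam = self.taxonomy.loc[keep].groupby(genus[keep])["family"].first() \
            if "family" in self.taxonomy.columns else None
        if fam is not None:
            tax["family"] = fam
        tax["rank"] = "genus"
        return FeatureTable(agg, tax)

    # -- IO ---------------------------------------------------------------
    def to_tsv(self, path) -> None:
        self.counts.to_csv(path, sep="\t", index_label="taxon")

    @classmethod
    def from_tsv(cls, path, taxonomy: pd.DataFrame | None = None) -> "FeatureTable":
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index.name = None
        return cls(counts, taxonomy)

    def __repr__(self) -> str:  # pragma: no cover
        return f"FeatureTable({self.shape[0]} taxa x {self.shape[1]} samples)"


def infer_taxonomy(taxa: pd.Index) -> pd.DataFrame:
    """Minimal species-rank taxonomy: genus = first token of the taxon name."""
    tax = pd.DataFrame(index=taxa)
    for r in RANKS:
        tax[r] = None
    tax["species"] = list(taxa)
    tax["genus"] = [str(t).split()[0] if " " in str(t) else None for t in taxa]
    tax["rank"] = "species"
    return tax


class SampleMetadata:
    """Per-sample covariates: role, subspecies, dataset, altitude, coordinates,
    processed read count, sex and age class.

    Wraps a DataFrame indexed by sample identifier.  ``role`` must be one of
    ``calculus``, ``extraction_blank``, ``library_blank``, ``museum_control``.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = pd.DataFrame(frame)
        if frame.index.has_duplicates:
            raise ValueError("duplicate sample identifiers in metadata")
        if "role" not in frame.columns:
            raise ValueError("metadata must define a role for every sample")
        bad = set(frame["role"].dropna()) - VALID_ROLES
        if bad or frame["role"].isna().any():
            raise ValueError(f"invalid sample roles: {sorted(bad) or 'missing'}")
        self.frame = frame

    @property
    def samples(self) -> pd.Index:
        return self.frame.index

    def role(self) -> pd.Series:
        return self.frame["role"]

    def calculus_samples(self) -> pd.Index:
        return self.frame.index[self.frame["role"] == "calculus"]

    def blank_samples(self) -> pd.Index:
        return self.frame.index[self.frame["role"].isin(BLANK_ROLES)]

    def museum_controls(self) -> pd.Index:
        return self.frame.index[self.frame["role"] == "museum_control"]

    def select(self, samples) -> "SampleMetadata":
        return SampleMetadata(self.frame.loc[list(samples)])

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index_label="sample")

    @classmethod
    def from_tsv(cls, path) -> "SampleMetadata":
        return cls(pd.read_csv(path, sep="\t", index_col=0))

    def __repr__(self) -> str:  # pragma: no cover
        return f"SampleMetadata({len(self.frame)} samples)"


@dataclass
class DistanceMatrix:
    """Symmetric sample-by-sample dissimilarity matrix with a metric tag."""

    ids: list[str]
    values: np.ndarray
    metric: str = "euclidean"

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        n = len(self.ids)
        if v.shape != (n, n):
            raise ValueError("distance matrix size does not match id list")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if np.abs(np.diag(v)).max(initial=0.0) > 1e-12:
            raise ValueError("distance matrix diagonal is not zero")
        if (v < -1e-12).any():
            raise ValueError("negative distances")
        v = np.clip((v + v.T) / 2.0, 0.0, None)
        np.fill_diagonal(v, 0.0)
        self.values = v
        self.ids = list(self.ids)

    @property
    def n(self) -> int:
        return len(self.ids)

    def condensed(self) -> np.ndarray:
        return squareform(self.values, checks=False)

    def select(self, ids) -> "DistanceMatrix":
        ids = list(ids)
        idx = [self.ids.index(i) for i in ids]
        return DistanceMatrix(ids, self.values[np.ix_(idx, idx)], self.metric)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def to_skbio(self):
        import skbio

        return skbio.DistanceMatrix(self.values, ids=self.ids)


# ---------------------------------------------------------------------------
# Compositional transform and distances
# ---------------------------------------------------------------------------

def clr_transform(
    table: FeatureTable | pd.DataFrame, pseudocount: float | None = None,
    allow_empty: bool = False,
) -> pd.DataFrame:
    """Centred log-ratio transform of per-sample compositions.

    Zeros are replaced multiplicatively with ``pseudocount`` (as a relative
    abundance); by default half the smallest nonzero relative abundance in the
    whole table.  Each output column (sample) sums to zero.

    Raises
    ------
    ValueError
        If any sample is all-zero (named in the message).  With
        ``allow_empty=True`` all-zero samples are instead given the uniform
        pseudocount composition (CLR zero vector) — appropriate for tables
        restricted to a small taxon panel where structural absences can empty
        a sample.
    """
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    totals = counts.sum(axis=0)
    empty = totals.index[totals == 0]
    if len(empty) and not allow_empty:
        raise ValueError(f"all-zero sample(s): {list(empty)}")
    rel = counts / totals.replace(0, np.nan)
    rel = rel.fillna(0.0)
    vals = rel.values.astype(float)
    nz = vals[vals > 0]
    if pseudocount is None:
        pseudocount = 0.5 * nz.min()
    vals = np.where(vals > 0, vals, pseudocount)
    log = np.log(vals)
    clr = log - log.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=counts.index, columns=counts.columns)


def _require_multiple_samples(counts: pd.DataFrame) -> None:
    if counts.shape[1] < 2:
        raise ValueError("at least two samples are required for a distance matrix")


def jaccard_distances(table: FeatureTable | pd.DataFrame) -> DistanceMatrix:
    """Jaccard distance ``1 - |A∩B| / |A∪B|`` on presence/absence (count > 0)."""
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    _require_multiple_samples(counts)
    pres = (counts.values > 0).T  # samples x taxa
    d = squareform(pdist(pres, metric="jaccard"))
    return DistanceMatrix(list(counts.columns), d, "jaccard")


def aitchison_distances(
    table: FeatureTable | pd.DataFrame, pseudocount: float | None = None,
    allow_empty: bool = False,
) -> DistanceMatrix:
    """Aitchison distance: Euclidean distance between CLR vectors."""
    counts = table.counts if isinstance(table, FeatureTable) else pd.DataFrame(table)
    _require_multiple_samples(counts)
    clr = clr_transform(counts, pseudocount=pseudocount, allow_empty=allow_empty)
    d = squareform(pdist(clr.values.T, metric="euclidean"))
    return DistanceMatrix(list(counts.columns), d, "aitchison")


def euclidean_distances(matrix: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between columns (samples) of a feature matrix."""
    _require_multiple_samples(matrix)
    d = squareform(pdist(matrix.values.T, metric="euclidean"))
    return DistanceMatrix(list(matrix.columns), d, "euclidean")


# ---------------------------------------------------------------------------
# Kraken2/Bracken-style report IO
# ---------------------------------------------------------------------------

_RANK_CODE = {"D": "kingdom", "K": "kingdom", "P": "phylum", "C": "class",
              "O": "order", "F": "family", "G": "genus", "S": "species"}


def read_kraken_report(path) -> pd.DataFrame:
    """Parse a Kraken2-style report into one sample's species-level counts.

    The report dialect has tab-separated columns ``percent, clade_reads,
    taxon_reads, rank_code, taxid, name`` with two-space indentation encoding
    the clade hierarchy.  Species-level (``S``) clade counts are returned with
    the lineage reconstructed from the indentation stack.  Genus-level rows are
    available separately through :func:`read_kraken_report_rank`.

    Returns a DataFrame indexed by species name with columns ``count`` and the
    lineage ranks.  Malformed rows raise a parse error naming the line number;
    an empty report returns an empty frame with a warning.
    """
    rows = _parse_kraken_rows(path)
    out = _rows_at_rank(rows, "S")
    if not len(out):
        warnings.warn(f"no species-level rows in report {path}")
    return out


def read_kraken_report_rank(path, rank_code: str = "G") -> pd.DataFrame:
    """Rows of a Kraken2-style report at one rank code (e.g. ``G`` for genus)."""
    return _rows_at_rank(_parse_kraken_rows(path), rank_code)


def _parse_kraken_rows(path):
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(f"{path}: malformed report row at line {lineno}")
            try:
                clade_reads = int(parts[1])
                taxid = int(parts[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed report row at line {lineno}"
                ) from exc
            name_field = parts[5]
            depth = (len(name_field) - len(name_field.lstrip(" "))) // 2
            rows.append(
                dict(clade_reads=clade_reads, rank=parts[3], taxid=taxid,
                     name=name_field.strip(), depth=depth, line=lineno)
            )
    return rows


def _rows_at_rank(rows, rank_code: str) -> pd.DataFrame:
    stack: list[dict] = []
    records = []
    for row in rows:
        while stack and stack[-1]["depth"] >= row["depth"]:
            stack.pop()
        stack.append(row)
        if row["rank"] == rank_code:
            lineage = {r: None for r in RANKS}
            for anc in stack:
                key = _RANK_CODE.get(anc["rank"][:1])
                if key and anc["rank"] in _RANK_CODE:
                    lineage[key] = anc["name"]
            rec = {"count": row["clade_reads"], "taxid": row["taxid"], **lineage}
            records.append((row["name"], rec))
    frame = pd.DataFrame.from_dict(dict(records), orient="index")
    if not len(frame):
        frame = pd.DataFrame(columns=["count", "taxid", *RANKS])
    return frame


def write_kraken_report(path, lineage_counts: pd.DataFrame) -> None:
    """Write a species table (with lineage columns) in the Kraken2 report dialect.

    Used to round-trip synthetic fixtures; clade counts above the species level
    are the sums over descendant species.
    """
    df = lineage_counts
    total = int(df["count"].sum())
    lines = []
    lines.append(f"100.00\t{total}\t0\tR\t1\troot")

    rank_codes = ["D", "P", "C", "O", "F", "G", "S"]

    def emit(level: int, frame: pd.DataFrame, depth: int, taxid_gen):
        # levels with entirely missing rank values are skipped transparently;
        # the parser reconstructs lineage from whichever ancestors are present
        if level >= len(rank_codes):
            return
        rank_name = _RANK_CODE[rank_codes[level]]
        col = frame[rank_name] if rank_name in frame.columns else pd.Series(
            [None] * len(frame), index=frame.index
        )
        missing = col.isna()
        if missing.any():
            emit(level + 1, frame[missing], depth, taxid_gen)
        for value, sub in frame[~missing].groupby(col[~missing], sort=True):
            clade = int(sub["count"].sum())
            pct = 100.0 * clade / total if total else 0.0
            if rank_codes[level] == "S":
                taxid = int(sub["taxid"].iloc[0]) if "taxid" in sub else next(taxid_gen)
                taxon = clade
            else:
                taxid = next(taxid_gen)
                taxon = 0
            indent = "  " * depth
            lines.append(
                f"{pct:.2f}\t{clade}\t{taxon}\t{rank_codes[level]}\t{taxid}\t{indent}{value}"
            )
            emit(level + 1, sub, depth + 1, taxid_gen)

    def _gen():
        t = 10_000
        while True:
            t += 1
            yield t

    emit(0, df, 1, _gen())
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")


def feature_table_from_reports(paths: dict[str, str]) -> FeatureTable:
    """Assemble a FeatureTable from per-sample Kraken2-style reports."""
    cols = {}
    lineages = {}
    for sample, path in paths.items():
        frame = read_kraken_report(path)
        cols[sample] = frame["count"]
        for taxon, row in frame.iterrows():
            lineages.setdefault(taxon, {r: row.get(r) for r in RANKS})
    counts = pd.DataFrame(cols).fillna(0).astype(np.int64)
    tax = pd.DataFrame.from_dict(lineages, orient="index").reindex(counts.index)
    tax["rank"] = "species"
    return FeatureTable(counts, tax)
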