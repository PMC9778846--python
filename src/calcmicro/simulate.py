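"""Synthetic dental-calculus metagenome generator with recorded ground truth.

Emulates the study design that the downstream pipeline expects: three gorilla
subspecies occupying distinct altitude bands (western lowland 300-500 masl,
Grauer's 600-2100 masl split at 1000 masl into low/high bands, mountain
3000-3800 masl), two processing batches ("new" and "published"), extraction and
library blanks, and four museum controls.  Taxa are drawn from oral,
environmental and laboratory pools; calculus samples are dominated by oral
taxa, blanks by laboratory contaminants and museum controls by environmental
taxa.  Counts are Dirichlet-multinomial: per-sample compositions are drawn from
a Dirichlet with concentration ``concentration`` around a base composition on
which group, batch and spike effects act multiplicatively on the (relative)
abundance scale, then counts are multinomial at a log-normally drawn depth.

Altitude-graded marker taxa are built in by default:

* *highland markers* — structurally absent from western lowland and low-altitude
  Grauer's samples, slightly enriched in mountain relative to high-altitude
  Grauer's gorillas;
* *lowland markers* — the mirror image (absent from mountain and high-altitude
  Grauer's);
* *graded markers* — present everywhere with a log-fold effect increasing with
  the altitude band.

Terminal deamination on reads (C→T decaying geometrically from the 5' end,
G→A from the 3' end) is simulated by :func:`simulate_damaged_reads`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .tables import FeatureTable, SampleMetadata, infer_taxonomy

GROUPS = ["western", "grauers_low", "grauers_high", "mountain"]
GROUP_SUBSPECIES = {
    "western": "western_lowland",
    "grauers_low": "grauers",
    "grauers_high": "grauers",
    "mountain": "mountain",
}
ALTITUDE_BANDS = {
    "western": (300, 500),
    "grauers_low": (600, 1000),
    "grauers_high": (1001, 2100),
    "mountain": (3000, 3800),
}
COORD_BOXES = {  # (lat_min, lat_max, lon_min, lon_max)
    "western": (-2.0, 2.0, 10.0, 15.0),
    "grauers_low": (-3.0, 0.0, 26.0, 29.0),
    "grauers_high": (-3.0, 0.0, 26.5, 29.0),
    "mountain": (-1.7, -1.2, 29.2, 29.8),
}
DATASETS = ["new", "published"]

# default altitude-graded marker design (log-fold effects on relative abundance)
_HIGHLAND = [f"Altimontia{i:02d} montis" for i in range(1, 7)]
_LOWLAND = [f"Vallisia{i:02d} sylvatica" for i in range(1, 7)]
_GRADED = [f"Clinalis{i:02d} gradiens" for i in range(1, 5)]
_BATCH = ["Batchia01 varians", "Batchia02 varians"]
_DUAL = ["Duplexia01 oralis", "Duplexia02 dubia"]  # oral genus also on contaminant list


def _default_spikes() -> list[tuple[str, str, float]]:
    # effects increase monotonically with altitude band, but the within-band
    # contrasts (mountain vs high Grauer's, western vs low Grauer's) are kept
    # small: those pairs are ecologically equivalent in this design
    spikes = [(t, "mountain", 0.15) for t in _HIGHLAND]
    spikes += [(t, "western", 0.15) for t in _LOWLAND]
    for t in _GRADED:
        spikes += [(t, "grauers_low", 0.15), (t, "grauers_high", 1.8), (t, "mountain", 1.95)]
    return spikes


def _default_structural_zeros() -> list[tuple[str, str]]:
    sz = [(t, g) for t in _HIGHLAND for g in ("western", "grauers_low")]
    sz += [(t, g) for t in _LOWLAND for g in ("mountain", "grauers_high")]
    return sz


def _default_batch_effects() -> list[tuple[str, str, float]]:
    return [(t, "published", 2.0) for t in _BATCH]


@dataclass
class DamageModel:
    """Terminal deamination model: probability ``p1 * decay**(position-1)`` at
    each position from the read end, plus a uniform background error rate."""

    p1: float = 0.1
    decay: float = 0.5
    background: float = 0.001

    def validate(self) -> None:
        for name in ("p1", "decay", "background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"damage model {name} must be in [0, 1]")
        if self.p1 + self.background > 1.0:
            raise ValueError("p1 + background must not exceed 1")


@dataclass
class SimConfig:
    """Configuration of the synthetic study.

    ``n_samples_per_group`` is per (subspecies x altitude-band) group, i.e. per
    entry of :data:`GROUPS`.  Pool sizes exclude the built-in marker taxa.
    """

    seed: int = 0
    n_samples_per_group: int = 8
    n_blanks: int = 8
    n_museum_controls: int = 4
    n_oral: int = 60
    n_environmental: int = 25
    n_laboratory: int = 20
    n_diet: int = 30
    spikes: list = field(default_factory=_default_spikes)
    structural_zeros: list = field(default_factory=_default_structural_zeros)
    batch_effects: list = field(default_factory=_default_batch_effects)
    depth_meanlog: float = 14.0
    depth_sdlog: float = 0.5
    blank_depth_meanlog: float = 11.0
    control_depth_meanlog: float = 12.0
    concentration: float = 50.0
    control_concentration: float = 20.0
    damage: DamageModel = field(default_factory=DamageModel)

    def validate(self) -> None:
        if self.concentration <= 0 or self.control_concentration <= 0:
            raise ValueError("Dirichlet concentration must be positive")
        if self.depth_sdlog < 0:
            raise ValueError("depth sd-log must be nonnegative")
        for v in (self.depth_meanlog, self.blank_depth_meanlog, self.control_depth_meanlog):
            if v <= 0:
                raise ValueError("depth mean-log parameters must be positive")
        if min(self.n_samples_per_group, self.n_museum_controls) < 1 or self.n_blanks < 2:
            raise ValueError("sample, blank and control counts must be positive")
        self.damage.validate()


@dataclass
class GroundTruth:
    """What the generator actually did, for checking recovery downstream."""

    oral_taxa: list
    environmental_taxa: list
    laboratory_taxa: list
    marker_taxa: list
    contaminant_genera: list
    oral_genera: list
    spikes: list
    structural_zeros: list
    batch_effects: list
    group_labels: dict
    reference_profiles: pd.DataFrame | None = None

    def __post_init__(self):
        overlap = set(self.oral_taxa) & set(self.laboratory_taxa)
        if overlap:
            raise ValueError(f"oral and laboratory pools overlap: {sorted(overlap)}")
        # every generated sample carries a group label (calculus) or a role tag
        if any(v is None for v in self.group_labels.values()):
            raise ValueError("every sample must have a group label")

    def to_json(self, path) -> None:
        payload = {k: v for k, v in asdict(self).items() if k != "reference_profiles"}
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, default=list)


def _taxon_pools(config: SimConfig):
    oral = []
    for g in range(config.n_oral // 2):
        oral += [f"Oralibacter{g:02d} buccalis", f"Oralibacter{g:02d} gingivae"]
    oral = oral[: config.n_oral]
    env = [f"Terrabacter{g:02d} humi" for g in range(config.n_environmental)]
    lab = [f"Labobacter{g:02d} reagentis" for g in range(config.n_laboratory)]
    markers = _HIGHLAND + _LOWLAND + _GRADED
    oral_all = oral + markers + _BATCH + _DUAL
    return oral_all, env, lab, markers


def simulate_profiles(config: SimConfig):
    """Simulate the taxon-by-sample count table, metadata and ground truth.

    Returns ``(FeatureTable, SampleMetadata, GroundTruth)``.  Column sums equal
    the drawn per-sample read depths; identical config and seed give identical
    output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    oral, env, lab, markers = _taxon_pools(config)
    taxa = oral + env + lab
    m = len(taxa)
    idx = {t: i for i, t in enumerate(taxa)}
    for t, _g, _e in list(config.spikes) + [(t, g, 0) for t, g in config.structural_zeros]:
        if t not in idx:
            raise ValueError(f"spiked/structural-zero taxon not in pool: {t}")

    # base per-taxon weights (log-normal), fixed marker weight for stable effects
    base = np.exp(rng.normal(0.0, 1.0, m))
    for t in markers + _BATCH + _DUAL:
        base[idx[t]] = 1.0
    pool_mass = np.ones(m)
    oral_set, env_set, lab_set = set(oral), set(env), set(lab)
    for i, t in enumerate(taxa):
        pool_mass[i] = 1.0 if t in oral_set else (0.05 if t in env_set else 0.02)
    w_calculus = base * pool_mass

    # group-level weights: spikes multiply, structural zeros null out
    group_w = {g: w_calculus.copy() for g in GROUPS}
    for t, g, e in config.spikes:
        group_w[g][idx[t]] *= np.exp(e)
    for t, g in config.structural_zeros:
        group_w[g][idx[t]] = 0.0

    env_idx = np.array([idx[t] for t in env])
    lab_idx = np.array([idx[t] for t in lab])
    oral_idx = np.array([idx[t] for t in oral])

    counts = {}
    meta_rows = {}
    group_labels = {}

    def draw_sample(weights, depth_meanlog, concentration):
        depth = max(1, int(np.round(rng.lognormal(depth_meanlog, config.depth_sdlog))))
        present = weights > 0
        alpha = concentration * weights[present] / weights[present].sum()
        p = rng.dirichlet(np.maximum(alpha, 1e-12))
        p = np.maximum(p, 0.0)
        p /= p.sum()
        c = np.zeros(m, dtype=np.int64)
        c[present] = rng.multinomial(depth, p)
        return c, depth

    s = 0
    for g in GROUPS:
        lo, hi = ALTITUDE_BANDS[g]
        lat0, lat1, lon0, lon1 = COORD_BOXES[g]
        for k in range(config.n_samples_per_group):
            sid = f"{g}_{k:02d}"
            dataset = DATASETS[s % 2]
            w = group_w[g].copy()
            for t, ds, e in config.batch_effects:
                if ds == dataset:
                    w[idx[t]] *= np.exp(e)
            # sporadic presence of contaminants in real samples
            w[lab_idx] *= rng.random(len(lab_idx)) < 0.3
            w[env_idx] *= rng.random(len(env_idx)) < 0.7
            c, depth = draw_sample(w, config.depth_meanlog, config.concentration)
            counts[sid] = c
            meta_rows[sid] = dict(
                role="calculus",
                subspecies=GROUP_SUBSPECIES[g],
                dataset=dataset,
                altitude=float(np.round(rng.uniform(lo, hi))),
                latitude=float(np.round(rng.uniform(lat0, lat1), 4)),
                longitude=float(np.round(rng.uniform(lon0, lon1), 4)),
                read_count=depth,
                sex=rng.choice(["F", "M"]),
                age_class=rng.choice(["adult", "juvenile"], p=[0.8, 0.2]),
            )
            group_labels[sid] = g
            s += 1

    for b in range(config.n_blanks):
        sid = f"blank_{b:02d}"
        role = "extraction_blank" if b % 2 == 0 else "library_blank"
        w = base * 0.0
        w[lab_idx] = base[lab_idx] * 20.0
        carry = rng.random(m) < 0.1
        w[carry & (w == 0)] = base[carry & (w == 0)] * 1.0
        c, depth = draw_sample(w, config.blank_depth_meanlog, config.concentration)
        counts[sid] = c
        meta_rows[sid] = dict(
            role=role, subspecies=None, dataset=DATASETS[b % 2], altitude=np.nan,
            latitude=np.nan, longitude=np.nan, read_count=depth, sex=None,
            age_class=None,
        )
        group_labels[sid] = "blank"

    for cix in range(config.n_museum_controls):
        sid = f"museum_{cix:02d}"
        w = np.zeros(m)
        w[env_idx] = base[env_idx] * 20.0
        w[oral_idx] = base[oral_idx] * 0.3 * (rng.random(len(oral_idx)) < 0.5)
        w[lab_idx] = np.maximum(
            w[lab_idx], base[lab_idx] * 0.2 * (rng.random(len(lab_idx)) < 0.2)
        )
        c, depth = draw_sample(w, config.control_depth_meanlog, config.control_concentration)
        counts[sid] = c
        meta_rows[sid] = dict(
            role="museum_control", subspecies=None, dataset="new", altitude=np.nan,
            latitude=np.nan, longitude=np.nan, read_count=depth, sex=None,
            age_class=None,
        )
        group_labels[sid] = "museum_control"

    count_df = pd.DataFrame(counts, index=taxa)
    taxonomy = infer_taxonomy(count_df.index)
    lab_genera = sorted({t.split()[0] for t in lab})
    oral_genera = sorted({t.split()[0] for t in oral})
    contaminant_genera = lab_genera + ["Duplexia"]
    flags = pd.DataFrame(index=count_df.index)
    flags["oral_db"] = [t.split()[0] in set(oral_genera) for t in count_df.index]
    flags["core_hominid"] = [t in set(oral[: max(4, len(oral) // 10)]) for t in count_df.index]
    flags["contaminant_list"] = [
        t.split()[0] in set(contaminant_genera) for t in count_df.index
    ]
    table = FeatureTable(count_df, taxonomy, flags)
    meta = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))

    refs = pd.DataFrame(index=taxa)
    for name, pool_ix in (("oral", oral_idx), ("environmental", env_idx), ("laboratory", lab_idx)):
        v = np.zeros(m)
        v[pool_ix] = base[pool_ix]
        refs[name] = v / v.sum()

    gt = GroundTruth(
        oral_taxa=list(oral),
        environmental_taxa=list(env),
        laboratory_taxa=list(lab),
        marker_taxa=list(markers),
        contaminant_genera=contaminant_genera,
        oral_genera=oral_genera,
        spikes=list(config.spikes),
        structural_zeros=list(config.structural_zeros),
        batch_effects=list(config.batch_effects),
        group_labels=group_labels,
        reference_profiles=refs,
    )
    return table, meta, gt


# ---------------------------------------------------------------------------
# Damaged-read simulation
# ---------------------------------------------------------------------------

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_A, _C, _G, _T = 0, 1, 2, 3
BARCODE_POS1_FACTOR = 0.25  # in-line barcodes suppress damage at position 1


@dataclass
class SimulatedReads:
    """Reads simulated against an internally generated reference.

    ``reads`` holds base codes (A=0, C=1, G=2, T=3), one row per read, all on
    the forward strand; ``starts`` are 0-based reference offsets sorted
    ascending.  ``ref_codes`` is the reference in the same encoding and
    ``damaged`` records whether the deamination process was active.
    """

    ref_codes: np.ndarray
    starts: np.ndarray
    reads: np.ndarray
    damaged: bool
    deaminated: np.ndarray  # per-read: carries >=1 deamination event
    ref_name: str = "ref1"

    @property
    def n_reads(self) -> int:
        return self.reads.shape[0]

    @property
    def read_length(self) -> int:
        return self.reads.shape[1]

    def ref_string(self) -> str:
        return _BASES[self.ref_codes].tobytes().decode()

    def write_fasta(self, path) -> None:
        seq = self.ref_string()
        with open(path, "w") as fh:
            fh.write(f">{self.ref_name}\n")
            for i in range(0, len(seq), 70):
                fh.write(seq[i : i + 70] + "\n")

    def write_sam(self, path) -> None:
        """Write sorted alignments in SAM format (full-length matches)."""
        import pysam

        header = {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": self.ref_name, "LN": int(len(self.ref_codes))}],
        }
        L = self.read_length
        with pysam.AlignmentFile(str(path), "w", header=header) as out:
            for i in range(self.n_reads):
                a = pysam.AlignedSegment(out.header)
                a.query_name = f"read{i:06d}"
                a.query_sequence = _BASES[self.reads[i]].tobytes().decode()
                a.reference_id = 0
                a.reference_start = int(self.starts[i])
                a.cigarstring = f"{L}M"
                a.mapping_quality = 60
                a.query_qualities = pysam.qualitystring_to_array("I" * L)
                out.write(a)


def simulate_damaged_reads(
    config: SimConfig,
    n_reads: int,
    damaged: bool = True,
    barcode_mode: bool = False,
    read_length: int = 60,
    ref_length: int = 5000,
    seed: int | None = None,
) -> SimulatedReads:
    """Simulate reads carrying terminal deamination against a random reference.

    When ``damaged``, C→T substitutions are applied near the 5' end and G→A
    near the 3' end with probability ``p1 * decay**(position-1)``; uniform
    background errors are applied at rate ``background`` regardless.  In
    ``barcode_mode`` the damage at terminal position 1 is suppressed (in-line
    barcodes absorb the terminal positions) and the decay profile starts at
    position 2.
    """
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    config.damage.validate()
    dm = config.damage
    rng = np.random.default_rng(config.seed if seed is None else seed)
    ref = rng.integers(0, 4, ref_length).astype(np.uint8)
    starts = np.sort(rng.integers(0, ref_length - read_length + 1, n_reads))
    reads = ref[starts[:, None] + np.arange(read_length)[None, :]].copy()

    deaminated = np.zeros(n_reads, dtype=bool)
    if damaged and dm.p1 > 0:
        pos = np.arange(read_length, dtype=float)
        p_end = dm.p1 * dm.decay**pos
        if barcode_mode:
            p_end = np.concatenate(
                [[dm.p1 * BARCODE_POS1_FACTOR], dm.p1 * dm.decay ** pos[:-1]]
            )
        p5 = p_end[None, :]
        p3 = p_end[::-1][None, :]
        u5 = rng.random(reads.shape)
        u3 = rng.random(reads.shape)
        ct = (reads == _C) & (u5 < p5)
        ga = (reads == _G) & (u3 < p3)
        reads[ct] = _T
        reads[ga] = _A
        deaminated = (ct | ga).any(axis=1)
    if dm.background > 0:
        hit = rng.random(reads.shape) < dm.background
        shift = rng.integers(1, 4, reads.shape).astype(np.uint8)
        reads[hit] = (reads[hit] + shift[hit]) % 4
    return SimulatedReads(ref, starts, reads, damaged, deaminated)


# ---------------------------------------------------------------------------
# Dietary table simulation
# ---------------------------------------------------------------------------

def simulate_diet_tables(config: SimConfig, meta: SampleMetadata | None = None,
                         group_labels: dict | None = None):
    """Simulate the genus-level eukaryote (dietary) table and its reference list.

    Returns ``(FeatureTable, reference)`` where ``reference`` is a DataFrame
    with columns ``genus, family, known_food_western, known_food_grauers,
    known_food_mountain``.  When ``meta``/``group_labels`` are omitted a fresh
    :func:`simulate_profiles` design is drawn with the same config.

    Subspecies-specific genera are enforced by construction: a western-only
    genus has zero counts in every mountain (and Grauer's) sample.
    """
    config.validate()
    if meta is None or group_labels is None:
        _, meta, gt = simulate_profiles(config)
        group_labels = gt.group_labels
    rng = np.random.default_rng(config.seed + 1)

    n = max(10, config.n_diet)
    genera, families = [], []
    for k in range(n):
        fam = f"Dietaceae{k // 2:02d}"
        genera.append(f"Dietgenus{k:02d}")
        families.append(fam)
    # habitat assignment: western-only, mountain-only, lowland- and
    # highland-shared (with Grauer's), and universal foods
    kinds = (["western_only"] * 4 + ["mountain_only"] * 4 + ["lowland"] * 6 +
             ["highland"] * 6 + ["universal"] * (n - 20))
    contam_genera = ["Molluscogenus01", "Molluscogenus02", "Shelfgenus01"]
    contam_families = ["Falsepositividae", "Falsepositividae", "Shelfidae"]

    present_in = {
        "western_only": {"western"},
        "mountain_only": {"mountain"},
        "lowland": {"western", "grauers_low", "grauers_high"},
        "highland": {"mountain", "grauers_low", "grauers_high"},
        "universal": set(GROUPS),
    }
    base = np.exp(rng.normal(0.0, 1.0, n))

    samples = [s for s, g in group_labels.items() if g in GROUPS or g == "museum_control"]
    all_genera = genera + contam_genera
    counts = pd.DataFrame(0, index=all_genera, columns=samples, dtype=np.int64)
    for sid in samples:
        g = group_labels[sid]
        depth = max(1, int(np.round(rng.lognormal(8.0, 0.6))))
        w = np.zeros(len(all_genera))
        if g == "museum_control":
            w[n:] = 5.0  # shelf/false-positive genera dominate controls
            w[:n] = base * 0.05 * (rng.random(n) < 0.3)
        else:
            for i in range(n):
                if g in present_in[kinds[i]]:
                    w[i] = base[i]
            w[n:] = 0.05 * (rng.random(len(contam_genera)) < 0.2)
        present = w > 0
        if not present.any():
            continue
        alpha = config.concentration * w[present] / w[present].sum()
        p = rng.dirichlet(np.maximum(alpha, 1e-12))
        counts.loc[np.array(all_genera)[present], sid] = rng.multinomial(
            depth, p / p.sum()
        )

    tax = pd.DataFrame(index=all_genera)
    tax["family"] = families + contam_families
    tax["genus"] = all_genera
    tax["rank"] = "genus"
    table = FeatureTable(counts, tax)

    ref = pd.DataFrame(
        dict(
            genus=genera,
            family=families,
            known_food_western=[kinds[i] in ("western_only", "lowland", "universal") for i in range(n)],
            known_food_grauers=[kinds[i] in ("lowland", "highland", "universal") for i in range(n)],
            known_food_mountain=[kinds[i] in ("mountain_only", "highland", "universal") for i in range(n)],
        )
    )
    return table, ref
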