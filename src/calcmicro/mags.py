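"""Provenance screening for metagenome-assembled genomes (MAGs).

Quality tiers follow the usual completeness/contamination cut-offs
(high: >90% / <5%; medium: >50% / <10%), isolation-source screening flags MAGs
whose public isolation records are dominated (>=25%) by environmental or
contaminant sources, and the museum-control exceedance rule mirrors the
taxon-level filter applied to abundance rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .tables import SampleMetadata

ISOLATION_CATEGORIES = ("contaminant", "environmental", "host-associated", "oral", "unknown")


@dataclass
class MagRecord:
    """One assembled genome: assignment, quality metrics, per-sample abundance
    and isolation-source category counts."""

    mag_id: str
    taxon: str | None = None
    completeness: float = 0.0
    contamination: float = 100.0
    abundance: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))
    isolation_sources: dict = field(default_factory=dict)

    def __post_init__(self):
        if not (0 <= self.completeness <= 100 and 0 <= self.contamination <= 100):
            raise ValueError("completeness and contamination must be in [0, 100]")
        bad = set(self.isolation_sources) - set(ISOLATION_CATEGORIES)
        if bad:
            raise ValueError(f"unknown isolation-source categories: {sorted(bad)}")
        if any(v < 0 for v in self.isolation_sources.values()):
            raise ValueError("isolation-source counts must be nonnegative")


def classify_mag_quality(mag: MagRecord) -> str:
    """Tier: ``high`` iff completeness > 90 and contamination < 5; else
    ``medium`` iff completeness > 50 and contamination < 10; else ``fail``."""
    if mag.completeness > 90 and mag.contamination < 5:
        return "high"
    if mag.completeness > 50 and mag.contamination < 10:
        return "medium"
    return "fail"


def isolation_source_screen(mag: MagRecord, threshold: float = 0.25) -> bool:
    """Flag as potential contaminant when the fraction of isolation records
    from contaminant or environmental sources is at least ``threshold``."""
    total = sum(mag.isolation_sources.values())
    if total == 0:
        raise ValueError(f"MAG {mag.mag_id} has no isolation records")
    bad = mag.isolation_sources.get("contaminant", 0) + mag.isolation_sources.get(
        "environmental", 0
    )
    return bad / total >= threshold


def mag_control_exceedance(
    abundances: pd.DataFrame, meta: SampleMetadata
) -> set:
    """MAGs found at strictly higher abundance in at least one museum control
    than in any calculus sample.  ``abundances`` is MAG x sample."""
    import warnings

    controls = [s for s in meta.museum_controls() if s in abundances.columns]
    if not controls:
        warnings.warn("no museum controls present; MAG exceedance is a no-op")
        return set()
    calculus = [s for s in meta.calculus_samples() if s in abundances.columns]
    ctrl_max = abundances[controls].max(axis=1)
    samp_max = (
        abundances[calculus].max(axis=1)
        if calculus
        else pd.Series(0.0, index=abundances.index)
    )
    return set(abundances.index[ctrl_max > samp_max])
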