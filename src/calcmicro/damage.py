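"""Terminal misincorporation profiles and ancient-DNA authentication.

Postmortem cytosine deamination elevates C→T substitution frequencies at the
5' end of sequencing reads and, on double-stranded libraries, complementary
G→A substitutions at the 3' end.  :func:`damage_profile` accumulates, for the
first K positions from each read end (counted along reference-aligned bases,
soft clips excluded), the opportunity counts (reference C for C→T, reference G
for G→A) and observed mismatches, for both substitution types at both ends.

A taxon/sample is called *authentic* when the damage frequency exceeds a
threshold (default 0.02) in at least ``min_hits`` (default 2) of the first
``positions`` (default 3) terminal positions on at least one end.  In-line
barcodes suppress damage at the first terminal position, so ``barcode_mode``
evaluates positions 2-4 instead.  Profiles with fewer classified reads than
the testability threshold (default 10,000) are *untestable* and conventionally
retained by callers.

The phrase pairing C→T with the 3' end appears in some descriptions of the
rule; the standard convention (as reported by mapDamage-style tools) pairs
C→T with the 5' end, which is the default here (``pairing="conventional"``),
with ``pairing="literal"`` evaluating the swapped assignment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .simulate import SimulatedReads, _C, _G, _T, _A

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass
class DamageProfile:
    """Per-end, per-position substitution opportunities and mismatches."""

    k: int
    n_reads: int
    opp5_c: np.ndarray
    mis5_ct: np.ndarray
    opp5_g: np.ndarray
    mis5_ga: np.ndarray
    opp3_c: np.ndarray
    mis3_ct: np.ndarray
    opp3_g: np.ndarray
    mis3_ga: np.ndarray

    @classmethod
    def empty(cls, k: int = 25) -> "DamageProfile":
        z = lambda: np.zeros(k, dtype=np.int64)  # noqa: E731
        return cls(k, 0, z(), z(), z(), z(), z(), z(), z(), z())

    def frequency(self, end: str, substitution: str) -> np.ndarray:
        """Mismatch frequency per position; NaN where there is no opportunity."""
        opp, mis = {
            ("5p", "CT"): (self.opp5_c, self.mis5_ct),
            ("5p", "GA"): (self.opp5_g, self.mis5_ga),
            ("3p", "CT"): (self.opp3_c, self.mis3_ct),
            ("3p", "GA"): (self.opp3_g, self.mis3_ga),
        }[(end, substitution)]
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(opp > 0, mis / np.maximum(opp, 1), np.nan)

    def to_frame(self):
        import pandas as pd

        rows = []
        for end in ("5p", "3p"):
            for sub in ("CT", "GA"):
                f = self.frequency(end, sub)
                opp = self.opp5_c if (end, sub) == ("5p", "CT") else None
                for pos in range(self.k):
                    rows.append(dict(end=end, substitution=sub, position=pos + 1,
                                     frequency=f[pos]))
        return pd.DataFrame(rows)


@dataclass
class AuthenticationCall:
    """Outcome of the terminal-damage rule for one taxon/sample."""

    call: str  # authentic | not_authentic | untestable
    end5_pass: bool | None
    end3_pass: bool | None
    reads_classified: int | None = None
    label: str | None = None


def damage_profile(alignments, reference, k: int = 25) -> DamageProfile:
    """Accumulate a :class:`DamageProfile` from alignments.

    Parameters
    ----------
    alignments
        Path to a SAM/BAM file, or an iterable of ``pysam.AlignedSegment``.
    reference
        Path to the reference FASTA, a mapping ``{name: sequence}``, or a bare
        sequence string (single-contig case).
    k
        Number of terminal positions tracked from each end.

    Positions are counted along reference-aligned bases (indels and soft clips
    do not advance the terminal position index); reverse-strand alignments are
    complemented and counted from the read's own 5' end.
    """
    refs = _load_reference(reference)
    prof = DamageProfile.empty(k)

    close = None
    if isinstance(alignments, (str, bytes)) or hasattr(alignments, "__fspath__"):
        import pysam

        handle = pysam.AlignmentFile(str(alignments), check_sq=False)
        reads = handle.fetch(until_eof=True)
        close = handle.close
    else:
        reads = alignments
    try:
        for read in reads:
            if read.is_unmapped or read.is_secondary or read.is_supplementary:
                continue
            name = read.reference_name
            if name not in refs:
                if None in refs and len(refs) == 1:
                    name = None
                else:
                    raise ValueError(f"alignment references unknown contig {name!r}")
            refseq = refs[name]
            qseq = read.query_sequence
            if qseq is None:
                continue
            qseq = qseq.upper()
            pairs = read.get_aligned_pairs(matches_only=True)
            if not pairs:
                continue
            if read.reference_end is not None and read.reference_end > len(refseq):
                raise ValueError("alignment extends beyond the reference sequence")
            npairs = len(pairs)
            rev = read.is_reverse
            for i, (qpos, rpos) in enumerate(pairs):
                rb = refseq[rpos].upper()
                qb = qseq[qpos]
                if rev:
                    rb = _COMPLEMENT.get(rb, "N")
                    qb = _COMPLEMENT.get(qb, "N")
                    d5 = npairs - 1 - i
                else:
                    d5 = i
                d3 = npairs - 1 - d5
                if d5 < k:
                    _tally(prof, "5p", d5, rb, qb)
                if d3 < k:
                    _tally(prof, "3p", d3, rb, qb)
            prof.n_reads += 1
    finally:
        if close is not None:
            close()
    return prof


def _tally(prof: DamageProfile, end: str, d: int, rb: str, qb: str) -> None:
    if rb == "C":
        (prof.opp5_c if end == "5p" else prof.opp3_c)[d] += 1
        if qb == "T":
            (prof.mis5_ct if end == "5p" else prof.mis3_ct)[d] += 1
    elif rb == "G":
        (prof.opp5_g if end == "5p" else prof.opp3_g)[d] += 1
        if qb == "A":
            (prof.mis5_ga if end == "5p" else prof.mis3_ga)[d] += 1


def _load_reference(reference) -> dict:
    if isinstance(reference, dict):
        return dict(reference)
    if isinstance(reference, str) and set(reference.upper()) <= set("ACGTN") and \
            "." not in reference and "/" not in reference and len(reference) > 200:
        return {None: reference}
    if hasattr(reference, "__fspath__") or isinstance(reference, (str, bytes)):
        import pysam

        with pysam.FastaFile(str(reference)) as fa:
            return {name: fa.fetch(name) for name in fa.references}
    raise TypeError("reference must be a FASTA path, a dict or a sequence string")


def profile_simulated(sim: SimulatedReads, k: int = 25) -> DamageProfile:
    """Vectorised :class:`DamageProfile` for :class:`SimulatedReads` (all
    forward-strand, full-length matches).  Equivalent to writing the reads to
    SAM and calling :func:`damage_profile`."""
    L = sim.read_length
    k_eff = min(k, L)
    refmat = sim.ref_codes[sim.starts[:, None] + np.arange(L)[None, :]]
    reads = sim.reads
    prof = DamageProfile.empty(k)

    is_c = refmat == _C
    is_g = refmat == _G
    ct = is_c & (reads == _T)
    ga = is_g & (reads == _A)
    # 5' distances are the leading columns, 3' distances the trailing columns
    prof.opp5_c[:k_eff] = is_c[:, :k_eff].sum(axis=0)
    prof.mis5_ct[:k_eff] = ct[:, :k_eff].sum(axis=0)
    prof.opp5_g[:k_eff] = is_g[:, :k_eff].sum(axis=0)
    prof.mis5_ga[:k_eff] = ga[:, :k_eff].sum(axis=0)
    rev_cols = L - 1 - np.arange(k_eff)
    prof.opp3_c[:k_eff] = is_c[:, rev_cols].sum(axis=0)
    prof.mis3_ct[:k_eff] = ct[:, rev_cols].sum(axis=0)
    prof.opp3_g[:k_eff] = is_g[:, rev_cols].sum(axis=0)
    prof.mis3_ga[:k_eff] = ga[:, rev_cols].sum(axis=0)
    prof.n_reads = sim.n_reads
    return prof


def authenticate(
    profile: DamageProfile,
    threshold: float = 0.02,
    positions: int = 3,
    min_hits: int = 2,
    barcode_mode: bool = False,
    pairing: str = "conventional",
    mode: str = "any",
    reads_classified: int | None = None,
    min_reads: int = 10_000,
    label: str | None = None,
) -> AuthenticationCall:
    """Apply the terminal-damage rule to a profile.

    An end passes when strictly more than ``min_hits - 1`` of the evaluated
    positions have frequency strictly above ``threshold``.  The overall call is
    *authentic* when at least one end passes (``mode="any"``; ``mode="all"``
    requires both).  ``barcode_mode`` shifts the evaluated window from
    positions 1..positions to 2..positions+1.
    """
    if reads_classified is not None and reads_classified < min_reads:
        return AuthenticationCall("untestable", None, None, reads_classified, label)
    if profile.n_reads == 0:
        return AuthenticationCall("untestable", None, None, reads_classified, label)
    lo = 1 if barcode_mode else 0
    window = slice(lo, lo + positions)
    if pairing == "conventional":
        f5 = profile.frequency("5p", "CT")[window]
        f3 = profile.frequency("3p", "GA")[window]
    elif pairing == "literal":
        f5 = profile.frequency("5p", "GA")[window]
        f3 = profile.frequency("3p", "CT")[window]
    else:
        raise ValueError("pairing must be 'conventional' or 'literal'")

    def end_pass(freqs: np.ndarray) -> bool | None:
        defined = freqs[~np.isnan(freqs)]
        if defined.size == 0:
            return None
        return int((defined > threshold).sum()) >= min_hits

    p5, p3 = end_pass(f5), end_pass(f3)
    if p5 is None and p3 is None:
        return AuthenticationCall("untestable", None, None, reads_classified, label)
    outcomes = [p for p in (p5, p3) if p is not None]
    ok = any(outcomes) if mode == "any" else all(outcomes)
    return AuthenticationCall(
        "authentic" if ok else "not_authentic", p5, p3, reads_classified, label
    )


def authenticate_frequencies(
    freqs, threshold: float = 0.02, min_hits: int = 2
) -> bool:
    """Convenience: apply the >threshold rule to one end's frequency vector."""
    f = np.asarray(freqs, dtype=float)
    f = f[~np.isnan(f)]
    return int((f > threshold).sum()) >= min_hits
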