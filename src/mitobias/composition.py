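"""Nucleotide composition, strand-asymmetry skews, and GC content by codon
position.

Skews measure compositional asymmetry between the two strands:
AT skew = (A - T)/(A + T), GC skew = (G - C)/(G + C), both computed on raw
counts of the reported strand.  A skew whose denominator is zero is
reported as missing (None), never as 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

from .genetic_code import CODON_TO_FAMILY, FAMILY_SIZE, codons_of
from .genomes import CodingSequence


@dataclass(frozen=True)
class CompositionSummary:
    counts: dict[str, int]          # A/C/G/T counts (N excluded)
    fractions: dict[str, float]     # percentages over non-N bases
    at_skew: float | None
    gc_skew: float | None


@dataclass(frozen=True)
class PositionalGC:
    gc1: float
    gc2: float
    gc3: float
    gc12: float
    gc3s: float

    @property
    def as_dict(self) -> dict[str, float]:
        return {"gc1": self.gc1, "gc2": self.gc2, "gc3": self.gc3,
                "gc12": self.gc12, "gc3s": self.gc3s}


def composition(seq: str) -> CompositionSummary:
    """Base composition and skews of a DNA sequence (N ignored)."""
    if not seq:
        raise ValueError("empty sequence")
    c = Counter(seq.upper())
    counts = {b: c.get(b, 0) for b in "ACGT"}
    total = sum(counts.values())
    if total == 0:
        raise ValueError("sequence contains no unambiguous bases")
    fractions = {b: 100.0 * counts[b] / total for b in "ACGT"}
    at = counts["A"] + counts["T"]
    gc = counts["G"] + counts["C"]
    at_skew = (counts["A"] - counts["T"]) / at if at else None
    gc_skew = (counts["G"] - counts["C"]) / gc if gc else None
    return CompositionSummary(counts, fractions, at_skew, gc_skew)


def skew_from_fractions(a_pct: float, t_pct: float) -> float:
    """Skew computed directly from printed percentage (or count) pairs."""
    if a_pct + t_pct == 0:
        raise ValueError("zero denominator")
    return (a_pct - t_pct) / (a_pct + t_pct)


def positional_gc(cds_set: Iterable[CodingSequence]) -> PositionalGC:
    """GC content at codon positions over a set of in-frame CDSs.

    Terminal stop codons are excluded; codons containing N are excluded
    entirely.  GC3s is the GC fraction at third positions of codons in
    synonymous families of size >= 2 — under the vertebrate mitochondrial
    code every sense codon qualifies, so GC3s differs from GC3 only when a
    different code or a restricted family set is configured.
    """
    gc_at = [0, 0, 0]
    n_codons = 0
    gc3s_num = 0
    gc3s_den = 0
    for cds in cds_set:
        for codon in codons_of(cds.coding_nt):
            if "N" in codon or codon not in CODON_TO_FAMILY:
                continue
            n_codons += 1
            for i, base in enumerate(codon):
                if base in "GC":
                    gc_at[i] += 1
            if FAMILY_SIZE[CODON_TO_FAMILY[codon]] >= 2:
                gc3s_den += 1
                if codon[2] in "GC":
                    gc3s_num += 1
    if n_codons == 0:
        raise ValueError("no valid codons")
    gc1, gc2, gc3 = (100.0 * g / n_codons for g in gc_at)
    gc3s = 100.0 * gc3s_num / gc3s_den if gc3s_den else float("nan")
    return PositionalGC(gc1=gc1, gc2=gc2, gc3=gc3, gc12=(gc1 + gc2) / 2.0, gc3s=gc3s)
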