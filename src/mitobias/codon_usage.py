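"""Codon-usage bias statistics under the vertebrate mitochondrial code.

The battery follows the standard comparative-mitogenomics toolkit:

* RSCU — relative synonymous codon usage, observed count divided by the
  even-usage expectation within each synonymous family.
* ENc — Wright's effective number of codons, from per-family codon
  "homozygosity" F; ranges from 22 (one codon per family) to 60 (even
  usage) for this code once six-fold amino acids are split into their
  two-fold + four-fold sub-families.
* The ENc null curve ENc*(s) = 2 + s + 29/(s^2 + (1-s)^2) expected under
  mutation pressure alone at third-position GC content s.
* The neutrality regression of GC12 on GC3: a slope near 1 means mutation
  pressure dominates, near 0 means selection does.
* P2 — the translational-efficiency index (WWC + SST)/(WWY + SSY), where
  W/S classify the first two codon positions as weak (A/T) or strong (G/C)
  and Y is a pyrimidine third position; P2 > 0.5 indicates translational
  selection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from scipy import stats

from .composition import PositionalGC
from .genetic_code import (
    CODON_TO_FAMILY,
    FAMILY_SIZE,
    FOURFOLD_FAMILIES,
    SENSE_CODONS,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    TWOFOLD_FAMILIES,
    codons_of,
)
from .genomes import CodingSequence

ENC_MIN = 22.0   # one codon per family: 14 + 8
ENC_MAX = 60.0   # even usage: 14/(1/2) + 8/(1/4)


@dataclass(frozen=True)
class CodonCountTable:
    """Codon counts over the 60 sense codons for one (species, gene) pair
    or a concatenation; stop codons are never counted."""

    label: tuple[str, str]
    counts: Mapping[str, int]

    def __post_init__(self) -> None:
        bad = set(self.counts) & STOP_CODONS
        if bad:
            raise ValueError(f"stop codons in count table: {sorted(bad)}")

    @property
    def total(self) -> int:
        return sum(self.counts.values())

    def get(self, codon: str) -> int:
        return self.counts.get(codon, 0)

    def family_counts(self, family: str) -> list[int]:
        return [self.get(c) for c in SYNONYMOUS_FAMILIES[family]]

    def __add__(self, other: "CodonCountTable") -> "CodonCountTable":
        merged = {c: self.get(c) + other.get(c) for c in SENSE_CODONS
                  if self.get(c) + other.get(c)}
        return CodonCountTable((self.label[0], "concatenated"), merged)


@dataclass(frozen=True)
class NeutralityFit:
    slope: float
    intercept: float
    r2: float
    n: int


def count_codons(cds: CodingSequence, label: tuple[str, str] | None = None) -> CodonCountTable:
    """Count sense codons of an in-frame CDS.  The start codon is included,
    a terminal complete stop is excluded, and codons containing N (or any
    stop codon arising from N-handling upstream) are skipped."""
    counts: dict[str, int] = {}
    for codon in codons_of(cds.coding_nt):
        if codon in CODON_TO_FAMILY:
            counts[codon] = counts.get(codon, 0) + 1
    return CodonCountTable(label or (cds.species, cds.gene), counts)


def rscu(table: CodonCountTable) -> dict[str, float | None]:
    """RSCU per codon: count / (family total / family size).  Families with
    zero total get missing values (None)."""
    values: dict[str, float | None] = {}
    for family, codons in SYNONYMOUS_FAMILIES.items():
        total = sum(table.get(c) for c in codons)
        for c in codons:
            values[c] = None if total == 0 else table.get(c) * len(codons) / total
    return values


def _family_f_hat(counts: Sequence[int]) -> float | None:
    """Wright's homozygosity estimator F = (n * sum p^2 - 1)/(n - 1); needs
    at least two codons observed in the family."""
    n = sum(counts)
    if n < 2:
        return None
    sum_p2 = sum((x / n) ** 2 for x in counts)
    f = (n * sum_p2 - 1.0) / (n - 1.0)
    return f if f > 0 else None


def enc_wright(table: CodonCountTable, min_codons: int = 100) -> tuple[float, bool]:
    """Wright's effective number of codons for one count table.

    Returns (ENc, low_confidence) where low_confidence flags tables with
    fewer than ``min_codons`` codons.  Families with < 2 observations (or a
    non-positive F) are imputed with their degeneracy-class mean; the
    estimate is capped at the code's theoretical maximum of 60.
    """
    f_by_class: dict[int, list[float]] = {2: [], 4: []}
    for family in TWOFOLD_FAMILIES + FOURFOLD_FAMILIES:
        f = _family_f_hat(table.family_counts(family))
        if f is not None:
            f_by_class[FAMILY_SIZE[family]].append(f)
    if not f_by_class[2] and not f_by_class[4]:
        raise ValueError(f"{table.label}: no family has enough codons for ENc")
    enc = 0.0
    for size, n_families in ((2, len(TWOFOLD_FAMILIES)), (4, len(FOURFOLD_FAMILIES))):
        fs = f_by_class[size]
        if not fs:
            # fall back on the other class mean scaled by the null ratio 1/size
            other = f_by_class[4 if size == 2 else 2]
            mean_f = sum(other) / len(other)
        else:
            mean_f = sum(fs) / len(fs)
        enc += n_families / mean_f
    return min(enc, ENC_MAX), table.total < min_codons


def enc_expected(gc3s: float) -> float:
    """Wright's expected ENc under mutation pressure alone at
    third-position GC content ``gc3s`` (a fraction in (0, 1))."""
    if not 0.0 < gc3s < 1.0:
        raise ValueError("gc3s must lie strictly between 0 and 1")
    s = gc3s
    return 2.0 + s + 29.0 / (s * s + (1.0 - s) * (1.0 - s))


def neutrality_fit(points: Iterable[tuple[float, float]]) -> NeutralityFit:
    """Ordinary least squares of GC12 (y) on GC3 (x), one point per species
    by default.  The slope is read as the share of mutation pressure in
    shaping codon usage (slope 0.14 -> 14% mutation, 86% selection)."""
    pts = list(points)
    if len(pts) < 3:
        raise ValueError("neutrality fit needs at least 3 points")
    x = [p[0] for p in pts]
    y = [p[1] for p in pts]
    if max(x) == min(x):
        raise ValueError("degenerate GC3 variance")
    res = stats.linregress(x, y)
    return NeutralityFit(slope=float(res.slope), intercept=float(res.intercept),
                         r2=float(res.rvalue) ** 2, n=len(pts))


_WEAK = frozenset("AT")
_STRONG = frozenset("GC")
_PYRIMIDINE = frozenset("CT")


def p2_index(table: CodonCountTable) -> float | None:
    """P2 = (WWC + SST)/(WWY + SSY) over codon counts; None when the
    denominator is zero.  Invariant under scaling of all counts."""
    num = 0
    den = 0
    for codon, x in table.counts.items():
        p1, p2, p3 = codon
        doublet_weak = p1 in _WEAK and p2 in _WEAK
        doublet_strong = p1 in _STRONG and p2 in _STRONG
        if not (doublet_weak or doublet_strong) or p3 not in _PYRIMIDINE:
            continue
        den += x
        if (doublet_weak and p3 == "C") or (doublet_strong and p3 == "T"):
            num += x
    if den == 0:
        return None
    return num / den


def usage_stats(table: CodonCountTable, gc: PositionalGC | None = None,
                min_codons: int = 100) -> dict[str, float | None]:
    """Bundle of per-table usage statistics (ENc, P2, and — when positional
    GC is supplied — the expected ENc at the observed GC3s)."""
    enc, low = enc_wright(table, min_codons=min_codons)
    out: dict[str, float | None] = {"enc": enc, "enc_low_confidence": float(low),
                                    "p2": p2_index(table)}
    if gc is not None:
        out.update(gc.as_dict)
        s = gc.gc3s / 100.0
        out["enc_expected"] = enc_expected(s) if 0.0 < s < 1.0 else math.nan
    return out
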