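"""Vertebrate mitochondrial genetic code (NCBI translation table 2).

The table differs from the standard code in four codons: AGA and AGG are
stop codons, ATA codes for Met and TGA codes for Trp.  That leaves 60 sense
codons.  For codon-usage statistics the two six-fold amino acids of the
standard code collapse here into split families: Leu is a two-fold (TTA/TTG)
plus a four-fold (CTN) family, and Ser is a four-fold (TCN) plus a two-fold
(AGT/AGC) family, because the third position alone cannot interconvert the
sub-families.  Under this split the code has 14 two-fold and 8 four-fold
synonymous families (14*2 + 8*4 = 60 codons), which fixes the range of the
effective number of codons at [22, 60].
"""

from __future__ import annotations

import itertools

BASES = "ACGT"
PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

STOP_CODONS = frozenset({"TAA", "TAG", "AGA", "AGG"})

#: codon -> one-letter amino acid, sense codons only (table 2)
CODON_TO_AA: dict[str, str] = {}

_TABLE2_DIFFS = {"AGA": "*", "AGG": "*", "ATA": "M", "TGA": "W"}

_STANDARD = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

for _codon, _aa in _STANDARD.items():
    _aa = _TABLE2_DIFFS.get(_codon, _aa)
    if _aa != "*":
        CODON_TO_AA[_codon] = _aa

SENSE_CODONS: tuple[str, ...] = tuple(sorted(CODON_TO_AA))
assert len(SENSE_CODONS) == 60

#: family name -> tuple of member codons, six-fold amino acids split by
#: first-two-base box (Leu2/Leu4, Ser2/Ser4)
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}

def _build_families() -> None:
    by_aa: dict[str, list[str]] = {}
    for codon in SENSE_CODONS:
        by_aa.setdefault(CODON_TO_AA[codon], []).append(codon)
    for aa, codons in sorted(by_aa.items()):
        boxes: dict[str, list[str]] = {}
        for c in codons:
            boxes.setdefault(c[:2], []).append(c)
        if len(boxes) == 1:
            SYNONYMOUS_FAMILIES[aa] = tuple(sorted(codons))
        else:
            # split family: suffix with the family size for clarity
            for prefix, members in sorted(boxes.items()):
                SYNONYMOUS_FAMILIES[f"{aa}{len(members)}_{prefix}"] = tuple(sorted(members))

_build_families()

#: codon -> its (split) family name
CODON_TO_FAMILY: dict[str, str] = {
    codon: fam for fam, codons in SYNONYMOUS_FAMILIES.items() for codon in codons
}

FAMILY_SIZE: dict[str, int] = {f: len(c) for f, c in SYNONYMOUS_FAMILIES.items()}

TWOFOLD_FAMILIES = tuple(f for f, n in FAMILY_SIZE.items() if n == 2)
FOURFOLD_FAMILIES = tuple(f for f, n in FAMILY_SIZE.items() if n == 4)
assert len(TWOFOLD_FAMILIES) == 14 and len(FOURFOLD_FAMILIES) == 8

_COMPLEMENT = str.maketrans("ACGTNRYSWKMBDHVacgtnryswkmbdhv",
                            "TGCANYRSWMKVHDBtgcanyrswmkvhdb")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def translate(nt: str) -> str:
    """Translate an in-frame sequence under table 2; '*' for stops, 'X' for
    codons containing anything outside ACGT."""
    aas = []
    for i in range(0, len(nt) - len(nt) % 3, 3):
        codon = nt[i:i + 3].upper()
        if codon in STOP_CODONS:
            aas.append("*")
        else:
            aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def codons_of(nt: str) -> list[str]:
    """Complete codons of an in-frame sequence (trailing partial ignored)."""
    return [nt[i:i + 3].upper() for i in range(0, len(nt) - len(nt) % 3, 3)]


IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


def iupac_match(consensus_char: str, base: str) -> bool:
    return base in IUPAC.get(consensus_char.upper(), "")


def is_transition(a: str, b: str) -> bool:
    """A<->G or C<->T substitution."""
    return ({a, b} <= PURINES or {a, b} <= PYRIMIDINES) and a != b


def all_codons() -> itertools.product:
    return itertools.product(BASES, repeat=3)
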