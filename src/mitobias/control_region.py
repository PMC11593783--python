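"""Structural analysis of (duplicated) mitochondrial control regions.

An avian control region is organized into three domains — ETAS (extended
termination-associated sequences), a Central conserved domain (F/E/D/C
boxes, CSBa, CSBb, Bird-box) and a CSB domain (conserved sequence block 1)
— and frequently carries variable-number tandem repeats (VNTRs).  In
accipitrid-like mitogenomes two control-region copies occur: CR1 between
tRNA-Thr and tRNA-Pro and CR2 between tRNA-Glu and tRNA-Phe.  A CR2 that
retains all three domains and high identity to CR1 indicates concerted
evolution of the duplicates (gene order GO-II); a CR2 reduced to repeats
and randomized sequence is a degenerate pseudo-control-region (GO-IV).

The consensus box library shipped with the package is synthetic (see
``data/box_library.synthetic.tsv``); supply a curated library for real
annotations.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio import Align

from .genetic_code import IUPAC, reverse_complement
from .genomes import AnnotatedMitogenome, intergenic_sequence

logger = logging.getLogger(__name__)

DOMAINS = ("ETAS", "Central", "CSB")

#: domain -> list of requirement groups; the domain is present when every
#: group has at least one hit box
DEFAULT_DOMAIN_RULES: dict[str, list[frozenset[str]]] = {
    "ETAS": [frozenset({"ETAS"})],
    "Central": [frozenset({"D-box"}), frozenset({"C-box", "CSBb"})],
    "CSB": [frozenset({"CSB1"})],
}


@dataclass(frozen=True)
class BoxDef:
    name: str
    consensus: str
    domain: str
    max_mismatch_fraction: float

    def __post_init__(self) -> None:
        if not self.consensus:
            raise ValueError(f"{self.name}: empty consensus")
        if not 0.0 <= self.max_mismatch_fraction < 0.5:
            raise ValueError(f"{self.name}: mismatch fraction out of range")

    @property
    def max_mismatches(self) -> int:
        return int(len(self.consensus) * self.max_mismatch_fraction)


@dataclass
class BoxLibrary:
    entries: list[BoxDef]

    @classmethod
    def load(cls, path=None) -> "BoxLibrary":
        """Load a plain-text library (name, IUPAC consensus, domain,
        max_mismatch_fraction, tab-separated); defaults to the synthetic
        library shipped with the package."""
        if path is None:
            text = (importlib.resources.files("mitobias.data")
                    / "box_library.synthetic.tsv").read_text()
        else:
            with open(path) as fh:
                text = fh.read()
        entries = []
        for line in text.splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            name, consensus, domain, frac = line.split("\t")
            entries.append(BoxDef(name, consensus.upper(), domain, float(frac)))
        return cls(entries)

    def get(self, name: str) -> BoxDef:
        for e in self.entries:
            if e.name == name:
                return e
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [e.name for e in self.entries]


@dataclass(frozen=True)
class BoxHit:
    box: str
    start: int
    end: int
    strand: str
    mismatches: int
    copy_index: int = 1


@dataclass(frozen=True)
class TandemRepeat:
    motif: str
    period: int
    copies: float
    start: int
    end: int
    purity: float

    @property
    def composition_class(self) -> str:
        """Lineage-marker classification of the repeat motif by base
        composition: AT-rich (AT fraction >= 0.9), T-rich (T fraction >=
        0.8), else 'mixed'."""
        m = self.motif.upper()
        if not m:
            return "mixed"
        t_frac = m.count("T") / len(m)
        at_frac = (m.count("A") + m.count("T")) / len(m)
        if t_frac >= 0.8:
            return "T-rich"
        if at_frac >= 0.9:
            return "AT-rich"
        return "mixed"


@dataclass
class CRProfile:
    which: str                       # "CR1" or "CR2"
    length: int
    hits: list[BoxHit] = field(default_factory=list)
    repeats: list[TandemRepeat] = field(default_factory=list)
    domains_present: set[str] = field(default_factory=set)


@dataclass(frozen=True)
class GOClassification:
    go_type: str                     # "GO-II", "GO-IV" or "other"
    cr1_cr2_identity: float | None   # percent
    rationale: str


# ---------------------------------------------------------------------------
# box scanning

def _mismatch_profile(seq: str, consensus: str) -> np.ndarray:
    """Mismatch count of the consensus against every window of seq
    (IUPAC-aware on the consensus side)."""
    n, m = len(seq), len(consensus)
    if n < m:
        return np.empty(0, dtype=int)
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    mismatch = np.zeros(n - m + 1, dtype=int)
    for j, cons_char in enumerate(consensus):
        allowed = np.array([ord(b) for b in IUPAC.get(cons_char, "")], dtype=np.uint8)
        window = arr[j:j + n - m + 1]
        ok = np.isin(window, allowed)
        mismatch += ~ok
    return mismatch


def _best_nonoverlapping(candidates: list[tuple[int, int, int, str]]) -> list[tuple[int, int, int, str]]:
    """Greedy best-scoring non-overlapping subset; candidates are
    (mismatches, start, end, strand) and lower mismatches win, ties to the
    leftmost."""
    chosen: list[tuple[int, int, int, str]] = []
    for cand in sorted(candidates):
        mm, s, e, strand = cand
        if all(e <= cs or s >= ce for _, cs, ce, _ in chosen):
            chosen.append(cand)
    return sorted(chosen, key=lambda c: c[1])


def scan_boxes(cr: str, lib: BoxLibrary) -> list[BoxHit]:
    """Sliding-window IUPAC-aware Hamming scan of every library box against
    both strands of a control-region sequence.  Overlapping hits of the
    same box collapse to the best-scoring non-overlapping set; surviving
    hits are numbered ``copy_index`` 1..k in coordinate order."""
    cr = cr.upper()
    n = len(cr)
    rc = reverse_complement(cr)
    hits: list[BoxHit] = []
    for box in lib.entries:
        m = len(box.consensus)
        cands: list[tuple[int, int, int, str]] = []
        for strand, seq in (("+", cr), ("-", rc)):
            profile = _mismatch_profile(seq, box.consensus)
            for pos in np.nonzero(profile <= box.max_mismatches)[0]:
                s, e = int(pos), int(pos) + m
                if strand == "-":
                    s, e = n - e, n - s
                cands.append((int(profile[pos]), s, e, strand))
        for idx, (mm, s, e, strand) in enumerate(_best_nonoverlapping(cands), start=1):
            hits.append(BoxHit(box.name, s, e, strand, mm, copy_index=idx))
    return sorted(hits, key=lambda h: (h.start, h.box))


# ---------------------------------------------------------------------------
# tandem repeats

def _consensus_and_purity(region: str, period: int) -> tuple[str, float]:
    """Column-majority consensus motif of a repeat region and the fraction
    of region positions matching it (ties break alphabetically)."""
    cols: list[dict[str, int]] = [dict() for _ in range(period)]
    for i, base in enumerate(region):
        col = cols[i % period]
        col[base] = col.get(base, 0) + 1
    motif = "".join(max(sorted(c), key=lambda b: c[b]) for c in cols)
    matches = sum(1 for i, base in enumerate(region) if base == motif[i % period])
    return motif, matches / len(region)


def find_tandem_repeats(cr: str, min_period: int = 2, max_period: int = 200,
                        min_copies: float = 2.0,
                        min_purity: float = 0.85) -> list[TandemRepeat]:
    """Period-scan tandem-repeat detector.

    For each candidate period p the sequence is compared against itself
    shifted by p; maximal runs whose match fraction stays above
    ``min_purity`` are candidate arrays.  Each candidate is re-scored
    against its column-majority consensus motif, and arrays explained by a
    smaller already-accepted period are suppressed.
    """
    cr = cr.upper()
    n = len(cr)
    if n == 0:
        return []
    arr = np.frombuffer(cr.encode(), dtype=np.uint8)
    accepted: list[TandemRepeat] = []
    for p in range(max(1, min_period), min(max_period, n - 1) + 1):
        if n - p < p * (min_copies - 1):
            break
        m = arr[:-p] == arr[p:]
        i = 0
        L = len(m)
        while i < L:
            if not m[i]:
                i += 1
                continue
            # grow a run while its match fraction can stay above threshold
            j = i
            matches = 0
            last_good = i - 1
            while j < L:
                if m[j]:
                    matches += 1
                    if matches / (j - i + 1) >= min_purity:
                        last_good = j
                elif (matches) / (j - i + 1) < min_purity:
                    break
                j += 1
            run_end = last_good + 1      # exclusive, in m-coordinates
            i_next = max(j, i + 1)
            run_len = run_end - i
            region_len = run_len + p
            copies = region_len / p
            start, end = i, i + region_len
            i = i_next
            if copies < min_copies or run_len <= 0:
                continue
            motif, purity = _consensus_and_purity(cr[start:end], p)
            if purity < min_purity:
                continue
            # suppress if a smaller-period repeat already explains the span
            overlap_covered = False
            for acc in accepted:
                ov = min(end, acc.end) - max(start, acc.start)
                if ov > 0 and ov >= 0.5 * region_len:
                    overlap_covered = True
                    break
            if not overlap_covered:
                accepted.append(TandemRepeat(motif=motif, period=p,
                                             copies=round(copies, 2),
                                             start=start, end=end,
                                             purity=purity))
    return sorted(accepted, key=lambda r: (r.start, r.period))


# ---------------------------------------------------------------------------
# identity, domains, gene-order class

def pairwise_identity(cr1: str, cr2: str, match: float = 1.0,
                      mismatch: float = -1.0, open_gap: float = -5.0,
                      extend_gap: float = -1.0) -> float:
    """Percent identity of a global alignment of two control-region copies;
    gap columns count in the denominator."""
    if not cr1 or not cr2:
        raise ValueError("empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    aln = aligner.align(cr1.upper(), cr2.upper())[0]
    counts = aln.counts()
    return 100.0 * counts.identities / aln.length


def classify_domains(profile: CRProfile,
                     rules: dict[str, list[frozenset[str]]] | None = None) -> set[str]:
    """Domains present in a scanned profile: a domain counts as present when
    every requirement group of its rule has at least one hit box."""
    rules = rules or DEFAULT_DOMAIN_RULES
    hit_names = {h.box for h in profile.hits}
    present = {domain for domain, groups in rules.items()
               if all(hit_names & group for group in groups)}
    profile.domains_present = present
    return present


def profile_cr(seq: str, which: str, lib: BoxLibrary,
               rules: dict[str, list[frozenset[str]]] | None = None,
               **repeat_kwargs) -> CRProfile:
    """Scan one control-region copy: box hits, domains, tandem repeats."""
    profile = CRProfile(which=which, length=len(seq))
    if seq:
        profile.hits = scan_boxes(seq, lib)
        profile.repeats = find_tandem_repeats(seq, **repeat_kwargs)
    classify_domains(profile, rules)
    return profile


CR1_ANCHORS = ("tRNA-Thr", "tRNA-Pro")
CR2_ANCHORS = ("tRNA-Glu", "tRNA-Phe")


def extract_cr_sequences(genome: AnnotatedMitogenome) -> tuple[str, str]:
    """(CR1, CR2) sequences located between their tRNA anchors."""
    cr1 = intergenic_sequence(genome, *CR1_ANCHORS)
    cr2 = intergenic_sequence(genome, *CR2_ANCHORS)
    return cr1, cr2


def classify_gene_order(genome: AnnotatedMitogenome, lib: BoxLibrary | None = None,
                        identity_threshold: float = 60.0) -> GOClassification:
    """GO-II vs GO-IV call for one genome.

    GO-II (concerted evolution): CR2 retains all three conserved domains
    and its identity to CR1 is at least the threshold.  GO-IV (degenerate
    duplicate): a CR2 span exists but fails either condition.  "other": no
    CR2 span at all.  A missing CR1 is an error — there is no reference
    copy to compare against.
    """
    lib = lib or BoxLibrary.load()
    cr1, cr2 = extract_cr_sequences(genome)
    if not cr1:
        raise ValueError(f"{genome.id}: no CR1 span between {CR1_ANCHORS}")
    if not cr2:
        return GOClassification("other", None, "no CR2 span between anchors")
    identity = pairwise_identity(cr1, cr2)
    domains = classify_domains(profile_cr(cr2, "CR2", lib))
    if domains == set(DOMAINS) and identity >= identity_threshold:
        return GOClassification("GO-II", identity,
                                f"CR2 has all domains, identity {identity:.1f}%")
    missing = sorted(set(DOMAINS) - domains)
    return GOClassification("GO-IV", identity,
                            f"CR2 missing {missing or 'nothing'}, "
                            f"identity {identity:.1f}%")


def cr_report(genomes: list[AnnotatedMitogenome], lib: BoxLibrary | None = None,
              identity_threshold: float = 60.0,
              **repeat_kwargs) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Control-region structure report across genomes.

    Returns (table, tracks): one table row per species with CR1/CR2 domain
    ticks, pairwise identity and GO class; and a BED-compatible track frame
    of box hits and tandem repeats within each CR copy.
    """
    lib = lib or BoxLibrary.load()
    rows = []
    tracks = []
    for g in genomes:
        row: dict[str, object] = {"species": g.id}
        try:
            cr1, cr2 = extract_cr_sequences(g)
            for which, seq in (("CR1", cr1), ("CR2", cr2)):
                profile = profile_cr(seq, which, lib, **repeat_kwargs)
                row[f"{which}_length"] = profile.length
                for domain in DOMAINS:
                    row[f"{which}_{domain}"] = domain in profile.domains_present
                for h in profile.hits:
                    tracks.append({"chrom": f"{g.id}:{which}", "start": h.start,
                                   "end": h.end,
                                   "name": f"{h.box}/{h.copy_index}",
                                   "score": h.mismatches, "strand": h.strand})
                for r in profile.repeats:
                    tracks.append({"chrom": f"{g.id}:{which}", "start": r.start,
                                   "end": r.end,
                                   "name": f"VNTR:{r.motif}x{r.copies:.1f}:{r.composition_class}",
                                   "score": round(100 * r.purity), "strand": "+"})
            go = classify_gene_order(g, lib, identity_threshold)
            row["identity_pct"] = (None if go.cr1_cr2_identity is None
                                   else round(go.cr1_cr2_identity, 1))
            row["go_type"] = go.go_type
            row["complete"] = True
        except Exception as exc:
            logger.warning("%s: CR report failed: %s", g.id, exc)
            row["complete"] = False
        rows.append(row)
    track_cols = ["chrom", "start", "end", "name", "score", "strand"]
    return (pd.DataFrame(rows),
            pd.DataFrame(tracks, columns=track_cols))


def write_bed(tracks: pd.DataFrame, path) -> None:
    tracks.to_csv(path, sep="\t", header=False, index=False)
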