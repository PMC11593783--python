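"""Pairwise evolutionary distances, nucleotide diversity, Ka/Ks estimation
and neighbor-joining trees.

Distances
---------
* K2P (Kimura two-parameter): d = -1/2 ln((1 - 2P - Q) sqrt(1 - 2Q)) with
  P and Q the transition and transversion proportions.
* TN93 (Tamura-Nei 1993): separate purine and pyrimidine transition terms
  with base frequencies estimated from the sequence pair; reduces to K2P
  when base frequencies are equal.
* pi (nucleotide diversity): mean pairwise per-site difference over all
  unordered pairs, with pairwise deletion of gap/N columns (Nei-Li).

Ka/Ks follows Nei-Gojobori (1986) under the vertebrate mitochondrial code:
per-codon synonymous site fractions from the nine single-base neighbors,
multi-hit codon pairs averaged over all shortest substitution pathways
(pathways through stop codons excluded), and a Jukes-Cantor correction
applied separately to pS and pN.  A ratio below 1 indicates purifying
selection, 1 neutrality, above 1 positive selection.

Tree building is Saitou-Nei neighbor joining with the standard Q criterion,
deterministic tie-breaking by smallest leaf-label pair, and negative branch
lengths clamped to zero with the deficit moved to the sister branch.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Mapping, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .genetic_code import (
    CODON_TO_AA,
    STOP_CODONS,
    is_transition,
    translate,
)
from .genomes import CodingSequence

logger = logging.getLogger(__name__)

_GAPLIKE = frozenset("-N")


# ---------------------------------------------------------------------------
# site-pattern counting and distance formulae

@dataclass(frozen=True)
class PairwiseCounts:
    sites: int
    P: float   # transition proportion
    Q: float   # transversion proportion


def pairwise_counts(a: str, b: str) -> PairwiseCounts:
    """Transition/transversion proportions with pairwise deletion of columns
    containing gaps or N in either sequence."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    a = a.upper()
    b = b.upper()
    sites = ts = tv = 0
    for x, y in zip(a, b):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        sites += 1
        if x != y:
            if is_transition(x, y):
                ts += 1
            else:
                tv += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    return PairwiseCounts(sites=sites, P=ts / sites, Q=tv / sites)


def k2p_distance(a: str, b: str) -> float | None:
    """Kimura two-parameter distance; None on saturation."""
    c = pairwise_counts(a, b)
    w1 = 1.0 - 2.0 * c.P - c.Q
    w2 = 1.0 - 2.0 * c.Q
    if w1 <= 0.0 or w2 <= 0.0:
        logger.warning("K2P saturated (P=%.3f Q=%.3f)", c.P, c.Q)
        return None
    return -0.5 * math.log(w1 * math.sqrt(w2))


def p_distance(a: str, b: str) -> float:
    c = pairwise_counts(a, b)
    return c.P + c.Q


def tn93_distance(a: str, b: str) -> float | None:
    """Tamura-Nei (1993) distance with base frequencies estimated from the
    pair; None on saturation or when a frequency class is absent."""
    if len(a) != len(b):
        raise ValueError("sequences must be aligned to equal length")
    a = a.upper()
    b = b.upper()
    counts = dict.fromkeys("ACGT", 0.0)
    sites = p1 = p2 = q = 0
    for x, y in zip(a, b):
        if x in _GAPLIKE or y in _GAPLIKE:
            continue
        sites += 1
        counts[x] += 0.5
        counts[y] += 0.5
        if x != y:
            if {x, y} == {"A", "G"}:
                p1 += 1
            elif {x, y} == {"C", "T"}:
                p2 += 1
            else:
                q += 1
    if sites == 0:
        raise ValueError("no comparable sites")
    g = {base: counts[base] / sites for base in "ACGT"}
    gr = g["A"] + g["G"]
    gy = g["C"] + g["T"]
    if min(gr, gy) <= 0 or min(g.values()) < 0:
        return None
    P1, P2, Q = p1 / sites, p2 / sites, q / sites
    k1 = 2.0 * g["A"] * g["G"] / gr if gr else 0.0
    k2 = 2.0 * g["C"] * g["T"] / gy if gy else 0.0
    k3 = 2.0 * (gr * gy - g["A"] * g["G"] * gy / gr - g["C"] * g["T"] * gr / gy)
    w1 = 1.0 - P1 / k1 - Q / (2.0 * gr) if k1 else 1.0
    w2 = 1.0 - P2 / k2 - Q / (2.0 * gy) if k2 else 1.0
    w3 = 1.0 - Q / (2.0 * gr * gy)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        logger.warning("TN93 saturated")
        return None
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


def nucleotide_diversity(alignment: Sequence[str]) -> float:
    """Nei-Li nucleotide diversity: mean pairwise per-site difference with
    pairwise deletion of gap/N columns."""
    if len(alignment) < 2:
        raise ValueError("need at least two sequences")
    total = 0.0
    n_pairs = 0
    for a, b in itertools.combinations(alignment, 2):
        total += p_distance(a, b)
        n_pairs += 1
    return total / n_pairs


# ---------------------------------------------------------------------------
# Nei-Gojobori (1986) Ka/Ks

@lru_cache(maxsize=None)
def _codon_sites(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon: the
    fraction of the three single-base neighbors at each position that are
    synonymous; neighbors that are stop codons count as nonsynonymous, so
    S + N = 3 for every codon."""
    aa = CODON_TO_AA[codon]
    s = 0.0
    for pos in range(3):
        for base in "ACGT":
            if base == codon[pos]:
                continue
            neighbor = codon[:pos] + base + codon[pos + 1:]
            if neighbor in STOP_CODONS:
                continue
            if CODON_TO_AA[neighbor] == aa:
                s += 1.0 / 3.0
    return s, 3.0 - s


@lru_cache(maxsize=None)
def _codon_pair_subs(c1: str, c2: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) substitution counts between two sense
    codons, averaged over all shortest pathways; pathways passing through a
    stop codon are excluded (all pathways are used if every one hits a
    stop)."""
    diff_pos = [i for i in range(3) if c1[i] != c2[i]]
    if not diff_pos:
        return 0.0, 0.0
    valid: list[tuple[int, int]] = []
    fallback: list[tuple[int, int]] = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        sd = nd = 0
        hit_stop = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1:]
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                hit_stop = True
                nd += 1  # stop-involving step tallied nonsynonymous (fallback only)
            elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if hit_stop:
            fallback.append((sd, nd))
        else:
            valid.append((sd, nd))
    paths = valid or fallback
    sd = sum(p[0] for p in paths) / len(paths)
    nd = sum(p[1] for p in paths) / len(paths)
    return sd, nd


def _jukes_cantor(p: float) -> float | None:
    if p >= 0.75:
        return None
    if p == 0.0:
        return 0.0
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


@dataclass(frozen=True)
class KaKsResult:
    ka: float | None
    ks: float | None
    s_sites: float
    n_sites: float
    sd: float
    nd: float
    codons: int

    @property
    def ratio(self) -> float | None:
        if self.ka is None or self.ks is None or self.ks == 0.0:
            return None
        return self.ka / self.ks


def ng86_ka_ks(a: CodingSequence | str, b: CodingSequence | str) -> KaKsResult:
    """Nei-Gojobori Ka/Ks between two codon-aligned coding sequences.

    Codons containing gaps or N in either sequence, and stop codons, are
    skipped.  pS or pN at or beyond the Jukes-Cantor ceiling of 3/4 yields
    a missing (None) rate.
    """
    nt_a = (a.coding_nt if isinstance(a, CodingSequence) else a).upper()
    nt_b = (b.coding_nt if isinstance(b, CodingSequence) else b).upper()
    if len(nt_a) != len(nt_b):
        raise ValueError("coding sequences must be codon-aligned to equal length")
    s_sites = n_sites = sd = nd = 0.0
    codons = 0
    for i in range(0, len(nt_a) - len(nt_a) % 3, 3):
        c1 = nt_a[i:i + 3]
        c2 = nt_b[i:i + 3]
        if (set(c1) | set(c2)) - set("ACGT"):
            continue
        if c1 in STOP_CODONS or c2 in STOP_CODONS:
            continue
        s1, n1 = _codon_sites(c1)
        s2, n2 = _codon_sites(c2)
        s_sites += (s1 + s2) / 2.0
        n_sites += (n1 + n2) / 2.0
        d_s, d_n = _codon_pair_subs(c1, c2)
        sd += d_s
        nd += d_n
        codons += 1
    if codons == 0:
        raise ValueError("no comparable codons")
    ps = sd / s_sites if s_sites else 0.0
    pn = nd / n_sites if n_sites else 0.0
    return KaKsResult(ka=_jukes_cantor(pn), ks=_jukes_cantor(ps),
                      s_sites=s_sites, n_sites=n_sites, sd=sd, nd=nd,
                      codons=codons)


# ---------------------------------------------------------------------------
# codon-aware alignment

def _protein_aligner(open_gap: float = -10.0, extend_gap: float = -0.5) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = open_gap
    aligner.extend_gap_score = extend_gap
    return aligner


def codon_align_pair(a: str, b: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment: translate under table 2, align the
    proteins globally, and thread the codons back through the protein
    alignment (gaps become codon-sized)."""
    if len(a) == len(b):
        return a, b
    prot_a = translate(a).replace("*", "X")
    prot_b = translate(b).replace("*", "X")
    aln = _protein_aligner().align(prot_a, prot_b)[0]
    rows = (str(aln[0]), str(aln[1]))
    out: list[list[str]] = [[], []]
    pos = [0, 0]
    for col in range(len(rows[0])):
        for k, seq in enumerate((a, b)):
            if rows[k][col] == "-":
                out[k].append("---")
            else:
                out[k].append(seq[pos[k] * 3:(pos[k] + 1) * 3])
                pos[k] += 1
    return "".join(out[0]), "".join(out[1])


# ---------------------------------------------------------------------------
# per-gene aggregation

@dataclass(frozen=True)
class GeneSelectionSummary:
    gene: str
    n_species: int
    mean_k2p: float | None
    pi: float
    ka: float | None
    ks: float | None
    ka_ks: float | None


def gene_summary(gene: str, cds_set: Mapping[str, CodingSequence | str],
                 ratio_mode: str = "mean_of_rates") -> GeneSelectionSummary:
    """One selection-table row for a gene across species: mean pairwise K2P,
    nucleotide diversity, and mean pairwise NG86 Ka and Ks.

    ``ratio_mode`` selects how the printed ratio aggregates pairs:
    ``mean_of_rates`` (default) divides mean Ka by mean Ks;
    ``mean_of_ratios`` averages per-pair ratios instead.
    """
    if len(cds_set) < 2:
        raise ValueError("need at least two species")
    species = sorted(cds_set)
    seqs: dict[str, str] = {}
    for sp in species:
        cds = cds_set[sp]
        seqs[sp] = cds.coding_nt if isinstance(cds, CodingSequence) else cds
    k2ps: list[float] = []
    kas: list[float] = []
    kss: list[float] = []
    ratios: list[float] = []
    aligned_pairs: list[tuple[str, str]] = []
    for sp1, sp2 in itertools.combinations(species, 2):
        try:
            a, b = codon_align_pair(seqs[sp1], seqs[sp2])
        except Exception:  # alignment failure drops the pair
            logger.warning("%s: alignment failed for %s vs %s", gene, sp1, sp2)
            continue
        aligned_pairs.append((a, b))
        d = k2p_distance(a, b)
        if d is not None:
            k2ps.append(d)
        kk = ng86_ka_ks(a, b)
        if kk.ka is not None and kk.ks is not None:
            kas.append(kk.ka)
            kss.append(kk.ks)
            if kk.ratio is not None:
                ratios.append(kk.ratio)
    pi = (sum(p_distance(a, b) for a, b in aligned_pairs) / len(aligned_pairs)
          if aligned_pairs else float("nan"))
    mean_ka = sum(kas) / len(kas) if kas else None
    mean_ks = sum(kss) / len(kss) if kss else None
    if ratio_mode == "mean_of_ratios":
        ka_ks = sum(ratios) / len(ratios) if ratios else None
    else:
        ka_ks = (mean_ka / mean_ks) if (mean_ka is not None and mean_ks) else None
    return GeneSelectionSummary(
        gene=gene, n_species=len(species),
        mean_k2p=sum(k2ps) / len(k2ps) if k2ps else None,
        pi=pi, ka=mean_ka, ks=mean_ks, ka_ks=ka_ks)


# ---------------------------------------------------------------------------
# distance matrices and neighbor joining

@dataclass
class DistanceMatrix:
    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValueError("matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("diagonal must be zero")

    @classmethod
    def from_sequences(cls, seqs: Mapping[str, str], model: str = "TN93",
                       align: bool = True) -> "DistanceMatrix":
        labels = sorted(seqs)
        dist = {"TN93": tn93_distance, "K2P": k2p_distance, "p": p_distance}[model]
        n = len(labels)
        d = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            a, b = seqs[labels[i]], seqs[labels[j]]
            if len(a) != len(b) and align:
                a, b = _align_dna(a, b)
            val = dist(a, b)
            if val is None:  # saturated: fall back on the p-distance ceiling
                val = p_distance(a, b)
                logger.warning("distance %s-%s saturated; using p-distance",
                               labels[i], labels[j])
            d[i, j] = d[j, i] = val
        return cls(labels, d)

    def to_phylip(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(f"{len(self.labels)}\n")
            for i, lab in enumerate(self.labels):
                row = " ".join(f"{x:.6f}" for x in self.d[i])
                fh.write(f"{lab:<12s}{row}\n")


def _align_dna(a: str, b: str) -> tuple[str, str]:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 1.0
    aligner.mismatch_score = -1.0
    aligner.open_gap_score = -5.0
    aligner.extend_gap_score = -1.0
    aln = aligner.align(a.upper(), b.upper())[0]
    return str(aln[0]), str(aln[1])


class _Node:
    __slots__ = ("newick", "min_label")

    def __init__(self, newick: str, min_label: str):
        self.newick = newick
        self.min_label = min_label


def _fmt(x: float) -> str:
    return f"{x:.6f}"


def nj_tree(dm: DistanceMatrix) -> str:
    """Saitou-Nei neighbor joining; returns an unrooted newick string with
    a trifurcating root.  Ties in the Q criterion break deterministically
    toward the pair with the lexicographically smallest leaf labels."""
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    nodes = [_Node(lab, lab) for lab in dm.labels]
    d = dm.d.copy()
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, j] for j in active if j != i) for i in active}
        best = None
        for ii, i in enumerate(active):
            for j in active[ii + 1:]:
                q = (m - 2) * d[i, j] - r[i] - r[j]
                key = (q, *sorted((nodes[i].min_label, nodes[j].min_label)))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        bi = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        bj = d[i, j] - bi
        if bi < 0.0:
            bj += bi
            bi = 0.0
        if bj < 0.0:
            bi += bj
            bj = 0.0
            bi = max(bi, 0.0)
        new_label = min(nodes[i].min_label, nodes[j].min_label)
        newick = f"({nodes[i].newick}:{_fmt(bi)},{nodes[j].newick}:{_fmt(bj)})"
        # grow matrix by one row/col for the merged node
        k = d.shape[0]
        d = np.pad(d, ((0, 1), (0, 1)))
        for x in active:
            if x in (i, j):
                continue
            d[k, x] = d[x, k] = 0.5 * (d[i, x] + d[j, x] - d[i, j])
        nodes.append(_Node(newick, new_label))
        active = [x for x in active if x not in (i, j)] + [k]

    a, b, c = sorted(active, key=lambda x: nodes[x].min_label)
    ba = 0.5 * (d[a, b] + d[a, c] - d[b, c])
    bb = 0.5 * (d[a, b] + d[b, c] - d[a, c])
    bc = 0.5 * (d[a, c] + d[b, c] - d[a, b])
    lens = [max(x, 0.0) for x in (ba, bb, bc)]
    parts = [f"{nodes[x].newick}:{_fmt(l)}" for x, l in zip((a, b, c), lens)]
    return f"({','.join(parts)});"
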