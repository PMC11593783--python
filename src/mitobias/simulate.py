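"""Synthetic mitogenome generator.

Produces inputs with the statistical structure the analysis stages assume:

* coding sequences with controlled codon-usage bias (per-family
  Dirichlet-multinomial synonymous codon choice; concentration alpha -> inf
  gives even usage / ENc near 60, alpha -> 0 one codon per family / ENc
  near 22);
* codon-level sequence divergence under a controlled dN/dS target omega and
  transition/transversion rate ratio kappa (proposal-acceptance scheme:
  kappa-weighted single-base proposals, stop-creating proposals rejected,
  nonsynonymous proposals accepted with probability min(1, omega)), with
  the true synonymous/nonsynonymous event counts recorded;
* fully annotated circular mitogenomes in the typical avian gene order
  (tRNA-Phe first; ND6 and eight tRNAs on the light strand) carrying one or
  two control regions with plantable conserved boxes and tandem repeats,
  and a degradation model for the second copy.

The model is deliberately stylized — uniform amino-acid frequencies, no
empirical codon exchangeabilities, random-sequence tRNA/rRNA placeholders —
which is sufficient to calibrate the estimators downstream.
"""

from __future__ import annotations

import io
import zlib
from dataclasses import dataclass, field, replace

import numpy as np
from Bio import Phylo

from .control_region import BoxLibrary
from .genetic_code import (
    CODON_TO_AA,
    IUPAC,
    STOP_CODONS,
    SYNONYMOUS_FAMILIES,
    reverse_complement,
)
from .genomes import AnnotatedMitogenome, CodingSequence, GeneFeature

#: approximate codon lengths of the 13 vertebrate mitochondrial PCGs
DEFAULT_GENE_LENGTHS: dict[str, int] = {
    "ND1": 326, "ND2": 346, "COI": 516, "COII": 227, "ATP8": 55,
    "ATP6": 227, "COIII": 261, "ND3": 116, "ND4L": 98, "ND4": 459,
    "ND5": 606, "ND6": 174, "Cytb": 380,
}

#: typical avian mitochondrial gene order starting at tRNA-Phe; CR1 sits
#: between tRNA-Thr and tRNA-Pro, CR2 between tRNA-Glu and tRNA-Phe
GENOME_LAYOUT: tuple[tuple[str, str, str], ...] = (
    ("tRNA-Phe", "tRNA", "+"),
    ("12S rRNA", "rRNA", "+"),
    ("tRNA-Val", "tRNA", "+"),
    ("16S rRNA", "rRNA", "+"),
    ("tRNA-Leu(UUR)", "tRNA", "+"),
    ("ND1", "CDS", "+"),
    ("tRNA-Ile", "tRNA", "+"),
    ("tRNA-Gln", "tRNA", "-"),
    ("tRNA-Met", "tRNA", "+"),
    ("ND2", "CDS", "+"),
    ("tRNA-Trp", "tRNA", "+"),
    ("tRNA-Ala", "tRNA", "-"),
    ("tRNA-Asn", "tRNA", "-"),
    ("tRNA-Cys", "tRNA", "-"),
    ("tRNA-Tyr", "tRNA", "-"),
    ("COI", "CDS", "+"),
    ("tRNA-Ser(UCN)", "tRNA", "-"),
    ("tRNA-Asp", "tRNA", "+"),
    ("COII", "CDS", "+"),
    ("tRNA-Lys", "tRNA", "+"),
    ("ATP8", "CDS", "+"),
    ("ATP6", "CDS", "+"),
    ("COIII", "CDS", "+"),
    ("tRNA-Gly", "tRNA", "+"),
    ("ND3", "CDS", "+"),
    ("tRNA-Arg", "tRNA", "+"),
    ("ND4L", "CDS", "+"),
    ("ND4", "CDS", "+"),
    ("tRNA-His", "tRNA", "+"),
    ("tRNA-Ser(AGY)", "tRNA", "+"),
    ("tRNA-Leu(CUN)", "tRNA", "+"),
    ("ND5", "CDS", "+"),
    ("Cytb", "CDS", "+"),
    ("tRNA-Thr", "tRNA", "+"),
    ("CR1", "control_region", "+"),
    ("tRNA-Pro", "tRNA", "-"),
    ("ND6", "CDS", "-"),
    ("tRNA-Glu", "tRNA", "-"),
    ("CR2", "control_region", "+"),
)

_FAMILIES = tuple(sorted(SYNONYMOUS_FAMILIES))
_MET_FAMILY = next(f for f, cs in SYNONYMOUS_FAMILIES.items() if "ATG" in cs)


@dataclass(frozen=True)
class CRPlan:
    """What to plant in a control-region copy."""
    length: int = 1200
    boxes: tuple[str, ...] = ("poly-C", "ETAS", "CSB1-like", "F-box", "E-box",
                              "D-box", "C-box", "CSBa", "CSBb", "Bird-box", "CSB1")
    repeat: tuple[str, int] | None = None      # (motif, copies) appended near 3'


@dataclass(frozen=True)
class DegradePlan:
    """CR2 degeneration model: substitutions/indels, box loss, repeat gain."""
    sub_rate: float = 0.3
    indel_rate: float = 0.02
    delete_boxes: frozenset[str] = frozenset({"ETAS", "D-box", "C-box", "CSBb", "CSB1"})
    expand_repeat: tuple[str, int] | None = ("TTTTA", 12)


@dataclass
class SimConfig:
    seed: int = 0
    n_species: int = 6
    gene_lengths: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GENE_LENGTHS))
    codon_bias: float = 5.0            # Dirichlet concentration alpha
    omega: float | dict[str, float] = 0.2
    kappa: float = 2.0
    branch_length: float = 0.05       # expected substitutions/site per edge
    tree: str | None = None           # newick with branch lengths; default balanced
    cr_plan: CRPlan = field(default_factory=CRPlan)
    go_type: str = "GO-II"            # layout of CR2: copy of CR1 or degraded
    degrade: DegradePlan = field(default_factory=DegradePlan)

    def omega_for(self, gene: str) -> float:
        if isinstance(self.omega, dict):
            return self.omega.get(gene, 0.2)
        return self.omega


@dataclass(frozen=True)
class EvolveRecord:
    """True event counts of one simulated branch."""
    syn_events: int
    nonsyn_events: int
    proposals: int


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ---------------------------------------------------------------------------
# coding sequences

def gen_cds(length_codons: int, codon_bias: float, seed, gene: str = "gene",
            species: str = "root") -> CodingSequence:
    """Random in-frame CDS with codon usage controlled by the Dirichlet
    concentration ``codon_bias``; the start codon is ATG, no stop codons
    occur, and a TAA terminal stop is appended."""
    if length_codons < 10:
        raise ValueError("need at least 10 codons")
    if codon_bias <= 0:
        raise ValueError("codon_bias (alpha) must be positive")
    rng = _rng(seed)
    probs: dict[str, np.ndarray] = {}
    for fam in _FAMILIES:
        k = len(SYNONYMOUS_FAMILIES[fam])
        probs[fam] = rng.dirichlet(np.full(k, codon_bias))
    fams = rng.integers(0, len(_FAMILIES), size=length_codons - 1)
    codons = ["ATG"]
    for fi in fams:
        fam = _FAMILIES[fi]
        members = SYNONYMOUS_FAMILIES[fam]
        codons.append(members[rng.choice(len(members), p=probs[fam])])
    nt = "".join(codons) + "TAA"
    return CodingSequence(gene=gene, species=species, nt=nt, complete_stop=True,
                          start_codon="ATG", stop_codon="TAA")


def evolve(cds: CodingSequence, t: float, omega: float = 1.0,
           kappa: float = 2.0, seed=0) -> tuple[CodingSequence, EvolveRecord]:
    """Evolve a CDS to an expected divergence of ``t`` substitutions/site.

    Single-base proposals are drawn uniformly over sites with a
    kappa-weighted base choice (transition probability kappa/(kappa + 2));
    proposals creating stop codons are rejected outright and nonsynonymous
    proposals are accepted with probability min(1, omega).  The number of
    accepted events is Poisson(t * length).
    """
    if t < 0:
        raise ValueError("t must be non-negative")
    rng = _rng(seed)
    seq = list(cds.coding_nt)
    L = len(seq)
    if L % 3:
        raise ValueError("CDS not in frame")
    n_target = int(rng.poisson(t * L)) if t > 0 else 0
    bases = "ACGT"
    transitions = {"A": "G", "G": "A", "C": "T", "T": "C"}
    transversions = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}
    accepted = syn = nonsyn = proposals = 0
    p_ts = kappa / (kappa + 2.0)
    while accepted < n_target:
        proposals += 1
        pos = int(rng.integers(0, L))
        old = seq[pos]
        if rng.random() < p_ts:
            new = transitions[old]
        else:
            new = transversions[old][int(rng.integers(0, 2))]
        codon_start = pos - pos % 3
        old_codon = "".join(seq[codon_start:codon_start + 3])
        new_codon = (old_codon[:pos - codon_start] + new
                     + old_codon[pos - codon_start + 1:])
        if new_codon in STOP_CODONS:
            continue
        synonymous = CODON_TO_AA[new_codon] == CODON_TO_AA[old_codon]
        if not synonymous and omega < 1.0 and rng.random() >= omega:
            continue
        seq[pos] = new
        accepted += 1
        if synonymous:
            syn += 1
        else:
            nonsyn += 1
    nt = "".join(seq) + (cds.nt[len(cds.coding_nt):])
    out = replace(cds, nt=nt, start_codon=nt[:3])
    return out, EvolveRecord(syn_events=syn, nonsyn_events=nonsyn,
                             proposals=proposals)


def _balanced_tree(labels: list[str], branch_length: float) -> str:
    """Newick for a balanced tree with equal edge lengths."""
    def join(ls: list[str]) -> str:
        if len(ls) == 1:
            return ls[0]
        mid = len(ls) // 2
        return f"({join(ls[:mid])}:{branch_length},{join(ls[mid:])}:{branch_length})"
    return join(labels) + ";"


def evolve_along_tree(root_genes: dict[str, CodingSequence], tree_newick: str,
                      omega: float | dict[str, float] = 1.0, kappa: float = 2.0,
                      seed=0) -> tuple[dict[str, dict[str, CodingSequence]],
                                      dict[tuple[str, str], EvolveRecord]]:
    """Evolve a set of root genes independently along every edge of a tree.

    Returns (species -> gene -> CDS, (leaf-or-clade-path, gene) -> event
    record for leaf-terminal edges).
    """
    rng = _rng(seed)
    tree = Phylo.read(io.StringIO(tree_newick), "newick")
    leaves: dict[str, dict[str, CodingSequence]] = {}
    records: dict[tuple[str, str], EvolveRecord] = {}

    def om(gene: str) -> float:
        return omega.get(gene, 1.0) if isinstance(omega, dict) else omega

    def walk(clade, genes: dict[str, CodingSequence]) -> None:
        t = clade.branch_length or 0.0
        evolved: dict[str, CodingSequence] = {}
        for gene in sorted(genes):
            child_seed = rng.integers(0, 2**31 - 1)
            evolved[gene], rec = evolve(genes[gene], t, omega=om(gene),
                                        kappa=kappa, seed=int(child_seed))
            if clade.is_terminal():
                records[(clade.name, gene)] = rec
        if clade.is_terminal():
            leaves[clade.name] = {
                g: replace(c, species=clade.name) for g, c in evolved.items()}
        else:
            for child in clade.clades:
                walk(child, evolved)

    walk(tree.root, root_genes)
    return leaves, records


# ---------------------------------------------------------------------------
# control regions

def _random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))


def _realize_consensus(consensus: str, rng: np.random.Generator) -> str:
    """Concrete DNA instance of an IUPAC consensus."""
    out = []
    for ch in consensus.upper():
        allowed = IUPAC.get(ch, "ACGT")
        out.append(allowed[int(rng.integers(0, len(allowed)))])
    return "".join(out)


def build_control_region(plan: CRPlan, lib: BoxLibrary | None = None,
                         seed=0) -> tuple[str, dict[str, tuple[int, int]]]:
    """Control-region sequence with the planned boxes planted left-to-right
    at evenly spread offsets; returns (sequence, box name -> (start, end))."""
    lib = lib or BoxLibrary.load()
    rng = _rng(seed)
    boxes = [lib.get(name) for name in plan.boxes]
    total_box = sum(len(b.consensus) for b in boxes)
    repeat_len = len(plan.repeat[0]) * plan.repeat[1] if plan.repeat else 0
    if total_box + repeat_len > plan.length:
        raise ValueError("planned boxes/repeats exceed the CR length")
    free = plan.length - total_box - repeat_len
    # split free space into one spacer before each box plus a 3' tail; the
    # repeat expansion, if any, goes just before the tail
    cuts = sorted(rng.integers(0, free + 1, size=len(boxes))) if boxes else []
    spacers = np.diff([0, *cuts, free])
    seq_parts: list[str] = []
    layout: dict[str, tuple[int, int]] = {}
    pos = 0
    for i, box in enumerate(boxes):
        spacer = _random_dna(rng, int(spacers[i]))
        seq_parts.append(spacer)
        pos += len(spacer)
        realized = _realize_consensus(box.consensus, rng)
        layout[box.name] = (pos, pos + len(realized))
        seq_parts.append(realized)
        pos += len(realized)
    if plan.repeat:
        motif, copies = plan.repeat
        seq_parts.append(motif * copies)
        pos += repeat_len
    tail = _random_dna(rng, int(spacers[-1]))
    seq_parts.append(tail)
    return "".join(seq_parts), layout


def degrade_cr(cr: str, sub_rate: float = 0.0, indel_rate: float = 0.0,
               delete_boxes: frozenset[str] | set[str] = frozenset(),
               expand_repeat: tuple[str, int] | None = None,
               layout: dict[str, tuple[int, int]] | None = None,
               seed=0) -> str:
    """Generative model of pseudo-control-region degeneration: point
    substitutions and short indels, excision of named planted boxes
    (replaced by random sequence of the same length, requires ``layout``),
    and a tandem-repeat expansion appended at the 3' end."""
    rng = _rng(seed)
    seq = list(cr.upper())
    if delete_boxes:
        if layout is None:
            raise ValueError("box deletion requires the planted layout")
        for name in sorted(delete_boxes):
            if name not in layout:
                continue
            s, e = layout[name]
            seq[s:e] = list(_random_dna(rng, e - s))
    n = len(seq)
    if sub_rate > 0:
        flips = rng.random(n) < sub_rate
        for i in np.nonzero(flips)[0]:
            alternatives = [b for b in "ACGT" if b != seq[i]]
            seq[int(i)] = alternatives[int(rng.integers(0, 3))]
    if indel_rate > 0:
        out: list[str] = []
        for ch in seq:
            r = rng.random()
            if r < indel_rate / 2.0:
                continue                       # deletion
            out.append(ch)
            if r > 1.0 - indel_rate / 2.0:     # insertion
                out.append("ACGT"[int(rng.integers(0, 4))])
        seq = out
    result = "".join(seq)
    if expand_repeat:
        motif, copies = expand_repeat
        result += motif * copies
    return result


# ---------------------------------------------------------------------------
# whole genomes

_TRNA_LEN = 70
_RRNA_LEN = {"12S rRNA": 975, "16S rRNA": 1590}


def gen_mitogenome(config: SimConfig, species: str = "sim1",
                   cds_by_gene: dict[str, CodingSequence] | None = None,
                   cr1: str | None = None, cr2: str | None = None,
                   lib: BoxLibrary | None = None) -> AnnotatedMitogenome:
    """Assemble one annotated circular mitogenome in the typical avian
    layout.  CDSs default to fresh draws under the configured codon bias;
    CR1 defaults to a fresh build from the plan and CR2 to either a copy of
    CR1 (GO-II) or its degraded form (GO-IV)."""
    lib = lib or BoxLibrary.load()
    rng = np.random.default_rng([config.seed, zlib.crc32(species.encode())])
    if cds_by_gene is None:
        cds_by_gene = {
            gene: gen_cds(n, config.codon_bias, rng, gene=gene, species=species)
            for gene, n in sorted(config.gene_lengths.items())
        }
    if cr1 is None:
        cr1, layout = build_control_region(config.cr_plan, lib, rng)
    else:
        layout = None
    if cr2 is None:
        if config.go_type == "GO-II":
            cr2 = cr1
        elif config.go_type == "GO-IV":
            d = config.degrade
            if layout is None:
                _, layout = build_control_region(config.cr_plan, lib, rng)
            cr2 = degrade_cr(cr1, d.sub_rate, d.indel_rate, d.delete_boxes,
                             d.expand_repeat, layout=layout, seed=rng)
        else:
            cr2 = ""
    parts: list[str] = []
    features: list[GeneFeature] = []
    pos = 0
    for name, kind, strand in GENOME_LAYOUT:
        if kind == "CDS":
            if name not in cds_by_gene:   # reduced gene sets stay valid
                continue
            block = cds_by_gene[name].nt
            if strand == "-":
                block = reverse_complement(block)
        elif kind == "tRNA":
            block = _random_dna(rng, _TRNA_LEN)
        elif kind == "rRNA":
            block = _random_dna(rng, _RRNA_LEN[name])
        else:
            block = cr1 if name == "CR1" else cr2
            if not block:
                continue
        feat_kind = kind if name != "CR2" else "pseudo_control_region"
        features.append(GeneFeature(name, feat_kind, pos, pos + len(block), strand))
        parts.append(block)
        pos += len(block)
    return AnnotatedMitogenome(species, "".join(parts), True, features)


@dataclass
class SimulatedDataset:
    genomes: list[AnnotatedMitogenome]
    cds_sets: dict[str, dict[str, CodingSequence]]   # species -> gene -> CDS
    tree: str
    truth: dict                                       # omega per gene, events


def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """End-to-end synthetic study: root genes, divergence along a tree with
    per-gene omega, and annotated genomes (with GO-II or GO-IV control
    regions) for every leaf species."""
    rng = _rng(config.seed)
    labels = [f"sp{i + 1:02d}" for i in range(config.n_species)]
    tree = config.tree or _balanced_tree(labels, config.branch_length)
    root_genes = {
        gene: gen_cds(n, config.codon_bias, rng, gene=gene)
        for gene, n in sorted(config.gene_lengths.items())
    }
    cds_sets, records = evolve_along_tree(root_genes, tree, omega=config.omega,
                                          kappa=config.kappa,
                                          seed=int(rng.integers(0, 2**31 - 1)))
    lib = BoxLibrary.load()
    cr1_root, layout = build_control_region(config.cr_plan, lib, rng)
    d = config.degrade
    cr2_root = (cr1_root if config.go_type == "GO-II" else
                degrade_cr(cr1_root, d.sub_rate, d.indel_rate, d.delete_boxes,
                           d.expand_repeat, layout=layout, seed=rng))
    genomes = []
    for sp in labels:
        # orthologous drift: small per-species noise on each CR copy
        cr1 = degrade_cr(cr1_root, sub_rate=0.02, seed=rng)
        cr2 = (cr1 if config.go_type == "GO-II"
               else degrade_cr(cr2_root, sub_rate=0.02, seed=rng))
        genomes.append(gen_mitogenome(config, species=sp,
                                      cds_by_gene=cds_sets[sp],
                                      cr1=cr1, cr2=cr2, lib=lib))
    truth = {
        "omega": {g: config.omega_for(g) for g in config.gene_lengths},
        "events": {f"{sp}:{g}": {"syn": r.syn_events, "nonsyn": r.nonsyn_events}
                   for (sp, g), r in sorted(records.items())},
        "go_type": config.go_type,
    }
    return SimulatedDataset(genomes=genomes, cds_sets=cds_sets, tree=tree,
                            truth=truth)
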