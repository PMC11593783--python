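"""Annotated mitochondrial genomes: GenBank/FASTA I/O, CDS extraction,
intergenic spans between tRNA anchors, and gene order.

Internal coordinates are 0-based half-open on the heavy strand; GenBank I/O
converts to/from the 1-based inclusive convention.  Features on circular
molecules may wrap the sequence origin (``wraps_origin``), in which case the
feature covers ``[start, len)`` followed by ``[0, end)``.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .genetic_code import STOP_CODONS, reverse_complement, translate

logger = logging.getLogger(__name__)

FEATURE_KINDS = ("CDS", "tRNA", "rRNA", "control_region", "pseudo_control_region")

#: canonical 13 mitochondrial protein-coding genes
PCG_NAMES = ("ND1", "ND2", "ND3", "ND4", "ND4L", "ND5", "ND6",
             "COI", "COII", "COIII", "ATP6", "ATP8", "Cytb")


class MitoParseError(ValueError):
    """Raised for malformed records or unresolvable features."""


class CDSValidationError(ValueError):
    """Raised when an extracted CDS fails table-2 translation checks."""


@dataclass(frozen=True)
class GeneFeature:
    name: str
    kind: str
    start: int
    end: int
    strand: str = "+"
    wraps_origin: bool = False

    def length(self, genome_length: int | None = None) -> int:
        if self.wraps_origin:
            if genome_length is None:
                raise ValueError("genome length required for a wrapping feature")
            return (genome_length - self.start) + self.end
        return self.end - self.start


@dataclass
class AnnotatedMitogenome:
    id: str
    sequence: str
    circular: bool = True
    features: list[GeneFeature] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        self.features.sort(key=lambda f: (f.start, f.end))
        self.validate()

    def validate(self) -> None:
        n = len(self.sequence)
        if n == 0:
            raise MitoParseError(f"{self.id}: empty sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise MitoParseError(f"{self.id}: non-ACGTN characters {sorted(bad)}")
        for f in self.features:
            if not (0 <= f.start < n and 0 <= f.end <= n):
                raise MitoParseError(f"{self.id}: feature {f.name} out of range")
            if not f.wraps_origin and f.start >= f.end:
                raise MitoParseError(f"{self.id}: feature {f.name} start >= end")

    def __len__(self) -> int:
        return len(self.sequence)

    def slice(self, feature: GeneFeature) -> str:
        """Heavy-strand sequence covered by a feature (wrap-aware)."""
        if feature.wraps_origin:
            return self.sequence[feature.start:] + self.sequence[:feature.end]
        return self.sequence[feature.start:feature.end]

    def find(self, name: str) -> list[GeneFeature]:
        return [f for f in self.features if f.name == name]

    def find_one(self, name: str) -> GeneFeature:
        hits = self.find(name)
        if len(hits) != 1:
            raise MitoParseError(
                f"{self.id}: expected exactly one feature named {name!r}, "
                f"found {len(hits)}: {[f'{h.start}-{h.end}' for h in hits]}")
        return hits[0]

    def rotated(self, offset: int) -> "AnnotatedMitogenome":
        """Rotate the circular sequence so that old position ``offset``
        becomes position 0; features are re-mapped accordingly."""
        n = len(self.sequence)
        offset %= n
        seq = self.sequence[offset:] + self.sequence[:offset]
        feats = []
        for f in self.features:
            s = (f.start - offset) % n
            length = f.length(n)
            e = s + length
            if e <= n:
                feats.append(replace(f, start=s, end=e, wraps_origin=False))
            else:
                feats.append(replace(f, start=s, end=e - n, wraps_origin=True))
        return AnnotatedMitogenome(self.id, seq, self.circular, feats)


@dataclass(frozen=True)
class CodingSequence:
    gene: str
    species: str
    nt: str
    complete_stop: bool
    start_codon: str
    stop_codon: str

    @property
    def coding_nt(self) -> str:
        """Sequence without the terminal stop codon (complete or trimmed)."""
        if self.complete_stop and self.nt[-3:] in STOP_CODONS:
            return self.nt[:-3]
        return self.nt


# ---------------------------------------------------------------------------
# gene-name canonicalization

def _load_synonyms() -> dict[str, str]:
    table: dict[str, str] = {}
    path = importlib.resources.files("mitobias.data") / "gene_synonyms.tsv"
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        alias, canonical = line.split("\t")
        table[alias.upper()] = canonical
    return table


_SYNONYMS: dict[str, str] | None = None


def canonical_gene_name(name: str) -> str:
    """Map an annotation label to the canonical symbol; unknown names pass
    through unchanged."""
    global _SYNONYMS
    if _SYNONYMS is None:
        _SYNONYMS = _load_synonyms()
    key = name.strip().upper().replace(" ", "")
    return _SYNONYMS.get(key, name.strip())


# ---------------------------------------------------------------------------
# GenBank I/O

_KIND_BY_KEY = {
    "CDS": "CDS",
    "tRNA": "tRNA",
    "rRNA": "rRNA",
    "D-loop": "control_region",
    "misc_feature": "control_region",
}


def _feature_name(feat: SeqFeature) -> str | None:
    for key in ("gene", "product", "note", "standard_name"):
        if key in feat.qualifiers:
            return str(feat.qualifiers[key][0])
    return None


def read_genbank(path) -> list[AnnotatedMitogenome]:
    """Parse a GenBank flat file into annotated mitogenomes.

    Feature names are canonicalized through the synonym table; unknown names
    are retained as-is with the kind inferred from the feature key and a log
    warning.  ``join()`` locations that span the origin become single
    wrapping features.
    """
    genomes = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise MitoParseError(f"malformed GenBank file {path}: {exc}") from exc
    if not records:
        raise MitoParseError(f"no records in {path}")
    for rec in records:
        feats: list[GeneFeature] = []
        n = len(rec.seq)
        for feat in rec.features:
            if feat.type not in _KIND_BY_KEY:
                continue
            raw = _feature_name(feat)
            if raw is None:
                logger.warning("%s: unnamed %s feature skipped", rec.id, feat.type)
                continue
            name = canonical_gene_name(raw)
            if name == raw and raw.upper() not in (name.upper(),):
                logger.info("%s: unknown gene name %r kept verbatim", rec.id, raw)
            kind = _KIND_BY_KEY[feat.type]
            if kind == "control_region" and name not in ("control_region", "CR1", "CR2"):
                # misc_feature that is not a control region: infer pseudo-CR
                if "pseudo" in raw.lower():
                    kind = "pseudo_control_region"
            strand = "-" if feat.location.strand == -1 else "+"
            loc = feat.location
            if isinstance(loc, CompoundLocation) and len(loc.parts) == 2:
                p1, p2 = loc.parts
                if int(p1.end) == n and int(p2.start) == 0:
                    feats.append(GeneFeature(name, kind, int(p1.start), int(p2.end),
                                             strand, wraps_origin=True))
                    continue
            feats.append(GeneFeature(name, kind, int(loc.start), int(loc.end), strand))
        circular = rec.annotations.get("topology", "circular") == "circular"
        genomes.append(AnnotatedMitogenome(rec.id, str(rec.seq), circular, feats))
    return genomes


def write_genbank(genomes: list[AnnotatedMitogenome], path) -> None:
    records = []
    for g in genomes:
        rec = SeqRecord(Seq(g.sequence), id=g.id, name=g.id[:16], description="")
        rec.annotations["molecule_type"] = "DNA"
        rec.annotations["topology"] = "circular" if g.circular else "linear"
        n = len(g.sequence)
        for f in g.features:
            strand = -1 if f.strand == "-" else 1
            if f.wraps_origin:
                loc = CompoundLocation([SimpleLocation(f.start, n, strand),
                                        SimpleLocation(0, f.end, strand)])
            else:
                loc = SimpleLocation(f.start, f.end, strand)
            key = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA",
                   "control_region": "D-loop",
                   "pseudo_control_region": "misc_feature"}[f.kind]
            sf = SeqFeature(loc, type=key, qualifiers={"gene": [f.name]})
            rec.features.append(sf)
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def read_fasta_with_table(fasta_path, table_path) -> list[AnnotatedMitogenome]:
    """Read sequences from FASTA plus a tab-separated feature table with
    columns name, kind, start, end, strand (1-based inclusive coordinates).
    All features are attached to the first record unless the table has a
    sixth column naming the record."""
    records = {rec.id: rec for rec in SeqIO.parse(str(fasta_path), "fasta")}
    if not records:
        raise MitoParseError(f"no sequences in {fasta_path}")
    first_id = next(iter(records))
    feats: dict[str, list[GeneFeature]] = {rid: [] for rid in records}
    with open(table_path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            name, kind, start, end, strand = parts[:5]
            rid = parts[5] if len(parts) > 5 else first_id
            feats[rid].append(GeneFeature(canonical_gene_name(name), kind,
                                          int(start) - 1, int(end), strand))
    return [AnnotatedMitogenome(rid, str(rec.seq), True, feats[rid])
            for rid, rec in records.items()]


# ---------------------------------------------------------------------------
# extraction

def extract_cds(genome: AnnotatedMitogenome, gene: str,
                species: str | None = None) -> CodingSequence:
    """Extract one protein-coding gene as an in-frame coding sequence.

    Minus-strand features are reverse-complemented so the returned ``nt`` is
    always the coding (message-sense) strand.  A trailing incomplete codon
    (T or TA, completed by post-transcriptional polyadenylation in vertebrate
    mitochondria) is recorded in ``stop_codon`` and trimmed from ``nt``.
    """
    feature = genome.find_one(gene)
    if feature.kind != "CDS":
        raise CDSValidationError(f"{gene} is annotated as {feature.kind}, not CDS")
    nt = genome.slice(feature)
    if feature.strand == "-":
        nt = reverse_complement(nt)
    remainder = len(nt) % 3
    if remainder:
        stop_codon = nt[-remainder:]
        nt = nt[:-remainder]
        complete_stop = False
    else:
        last = nt[-3:]
        if last in STOP_CODONS:
            stop_codon = last
            complete_stop = True
        else:
            stop_codon = ""
            complete_stop = False
    aa = translate(nt[:-3] if complete_stop else nt)
    if "*" in aa:
        idx = aa.index("*")
        raise CDSValidationError(
            f"{genome.id}:{gene}: internal stop codon at codon {idx}")
    return CodingSequence(gene=gene, species=species or genome.id, nt=nt,
                          complete_stop=complete_stop, start_codon=nt[:3],
                          stop_codon=stop_codon)


def locate_intergenic(genome: AnnotatedMitogenome, left_anchor: str,
                      right_anchor: str, name: str | None = None) -> GeneFeature:
    """Noncoding span strictly between two anchor genes in genome order,
    honoring circularity.  Overlapping anchors yield a zero-length span."""
    left = genome.find_one(left_anchor)
    right = genome.find_one(right_anchor)
    n = len(genome)
    start = left.end % n
    end = right.start % n
    if name is None:
        name = f"intergenic:{left_anchor}-{right_anchor}"
    if start == end:
        return GeneFeature(name, "control_region", start, start if start < n else 0, "+")
    if start < end:
        return GeneFeature(name, "control_region", start, end, "+")
    if not genome.circular:
        # anchors out of order on a linear molecule: treat as empty
        return GeneFeature(name, "control_region", start, start, "+")
    # span wraps the origin; guard against anchors overlapping circularly
    gap = (end - start) % n
    left_len = left.length(n)
    if gap > n - left_len - right.length(n):
        return GeneFeature(name, "control_region", start, start, "+")
    if end == 0:
        return GeneFeature(name, "control_region", start, n, "+")
    return GeneFeature(name, "control_region", start, end, "+", wraps_origin=True)


def intergenic_sequence(genome: AnnotatedMitogenome, left_anchor: str,
                        right_anchor: str) -> str:
    feat = locate_intergenic(genome, left_anchor, right_anchor)
    if feat.length(len(genome)) == 0:
        return ""
    return genome.slice(feat)


def gene_order(genome: AnnotatedMitogenome,
               origin_gene: str = "tRNA-Phe") -> list[tuple[str, str]]:
    """Features in circular order starting at ``origin_gene`` (by convention
    tRNA-Phe, the first gene of the typical avian arrangement)."""
    feats = sorted(genome.features, key=lambda f: (f.start, f.end))
    names = [f.name for f in feats]
    try:
        pivot = names.index(origin_gene)
    except ValueError:
        pivot = 0
    ordered = feats[pivot:] + feats[:pivot]
    return [(f.name, f.strand) for f in ordered]


def write_gene_order(genomes: list[AnnotatedMitogenome], path) -> None:
    """Gene-order lists as TSV: species, position, gene, strand."""
    with open(path, "w") as fh:
        fh.write("species\tposition\tgene\tstrand\n")
        for g in genomes:
            for i, (name, strand) in enumerate(gene_order(g)):
                fh.write(f"{g.id}\t{i}\t{name}\t{strand}\n")
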