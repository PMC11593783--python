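"""End-to-end analysis pipeline.

Consumes annotated mitogenomes and emits the standard comparative result
surfaces as plain TSV/newick/BED artifacts: composition and skews, the
RSCU matrix, per-gene usage statistics (ENc, positional GC, P2), the
GC12~GC3 neutrality regression, the per-gene selection table (mean K2P,
pi, Ka, Ks, Ka/Ks), the control-region structure report with GO
classification, a neighbor-joining tree of CR copies, and motif tracks.

Every table carries provenance columns (source label and a config hash)
and the whole bundle is deterministic for a fixed input + config.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import codon_usage as cu
from . import control_region as cr
from . import selection as sel
from .composition import composition as composition_of, positional_gc
from .genomes import AnnotatedMitogenome, PCG_NAMES, extract_cds, write_gene_order

logger = logging.getLogger(__name__)

ARTIFACTS = ("composition.tsv", "rscu_matrix.tsv", "usage_stats.tsv",
             "neutrality_fit.tsv", "selection_table.tsv", "cr_table.tsv",
             "cr_tree.nwk", "motif_tracks.bed")


@dataclass
class RunConfig:
    genes: tuple[str, ...] = PCG_NAMES
    outdir: str | Path = "mitobias_out"
    seed: int = 0
    identity_threshold: float = 60.0
    enc_min_codons: int = 100
    repeat_min_period: int = 2
    repeat_max_period: int = 200
    repeat_min_copies: float = 2.0
    repeat_min_purity: float = 0.85
    paper_compat: bool = False   # exclude light-strand ND6 from concatenated usage stats
    stages: tuple[str, ...] = ("composition", "usage", "selection", "cr")
    ratio_mode: str = "mean_of_rates"

    @property
    def config_hash(self) -> str:
        """Hash of the analysis parameters (output location excluded, so
        identical analyses hash identically wherever they are written)."""
        payload = dataclasses.asdict(self)
        payload.pop("outdir")
        payload = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _with_provenance(df: pd.DataFrame, source: str, cfg: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["source"] = source
    df["config_hash"] = cfg.config_hash
    return df


def _usage_genes(cfg: RunConfig) -> tuple[str, ...]:
    if cfg.paper_compat:
        return tuple(g for g in cfg.genes if g != "ND6")
    return cfg.genes


def run_all(genomes: list[AnnotatedMitogenome], config: RunConfig | None = None,
            source: str = "memory") -> dict[str, Path]:
    """Run every enabled stage and write the artifact bundle to
    ``config.outdir``; returns artifact name -> path for files written.
    Stage failures are isolated: the bundle simply lacks that artifact."""
    cfg = config or RunConfig()
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    # extract CDSs once; species with a missing/invalid gene are logged
    cds: dict[str, dict[str, object]] = {g.id: {} for g in genomes}
    for g in genomes:
        for gene in cfg.genes:
            try:
                cds[g.id][gene] = extract_cds(g, gene)
            except Exception as exc:
                logger.warning("%s: cannot extract %s: %s", g.id, gene, exc)

    def emit(name: str, df: pd.DataFrame) -> None:
        path = outdir / name
        _with_provenance(df, source, cfg).to_csv(path, sep="\t", index=False,
                                                 float_format="%.6g")
        written[name] = path

    if "composition" in cfg.stages:
        try:
            rows = []
            for g in genomes:
                s = composition_of(g.sequence)
                rows.append({"species": g.id, "unit": "genome",
                             **{b: round(s.fractions[b], 1) for b in "ACGT"},
                             "at_skew": round(s.at_skew, 4),
                             "gc_skew": round(s.gc_skew, 4)})
                concat = "".join(cds[g.id][x].coding_nt
                                 for x in _usage_genes(cfg) if x in cds[g.id])
                if concat:
                    s2 = composition_of(concat)
                    gc = positional_gc(
                        [cds[g.id][x] for x in _usage_genes(cfg) if x in cds[g.id]])
                    rows.append({"species": g.id, "unit": "concatenated_pcg",
                                 **{b: round(s2.fractions[b], 1) for b in "ACGT"},
                                 "at_skew": round(s2.at_skew, 4),
                                 "gc_skew": round(s2.gc_skew, 4),
                                 **{k: round(v, 2) for k, v in gc.as_dict.items()}})
            emit("composition.tsv", pd.DataFrame(rows))
        except Exception:
            logger.exception("composition stage failed")

    if "usage" in cfg.stages:
        try:
            rscu_cols = {}
            stats_rows = []
            points = []
            for g in genomes:
                tables = {gene: cu.count_codons(c)
                          for gene, c in cds[g.id].items()}
                if not tables:
                    continue
                concat_genes = [x for x in _usage_genes(cfg) if x in tables]
                concat = None
                for gene in concat_genes:
                    concat = tables[gene] if concat is None else concat + tables[gene]
                if concat is not None:
                    rscu_cols[g.id] = cu.rscu(concat)
                    gc = positional_gc([cds[g.id][x] for x in concat_genes])
                    points.append((gc.gc3, gc.gc12))
                for gene, table in sorted(tables.items()):
                    gc = positional_gc([cds[g.id][gene]])
                    row = {"species": g.id, "gene": gene, "n_codons": table.total}
                    row.update({k: (round(v, 4) if v == v else v) if v is not None else None
                                for k, v in cu.usage_stats(
                                    table, gc, min_codons=cfg.enc_min_codons).items()})
                    stats_rows.append(row)
            emit("usage_stats.tsv", pd.DataFrame(stats_rows))
            if rscu_cols:
                rscu_df = pd.DataFrame(rscu_cols).round(4)
                rscu_df.index.name = "codon"
                emit("rscu_matrix.tsv", rscu_df.reset_index())
            if len(points) >= 3:
                fit = cu.neutrality_fit(points)
                emit("neutrality_fit.tsv", pd.DataFrame([{
                    "slope": round(fit.slope, 4),
                    "intercept": round(fit.intercept, 4),
                    "r2": round(fit.r2, 4), "n_points": fit.n,
                    "x_variable": "GC3", "y_variable": "GC12"}]))
        except Exception:
            logger.exception("usage stage failed")

    if "selection" in cfg.stages:
        try:
            rows = []
            for gene in cfg.genes:
                per_species = {sp: c for sp, by_gene in cds.items()
                               for gn, c in by_gene.items() if gn == gene}
                if len(per_species) < 2:
                    continue
                s = sel.gene_summary(gene, per_species, ratio_mode=cfg.ratio_mode)
                rows.append({"gene": gene, "n_species": s.n_species,
                             "mean_k2p": s.mean_k2p, "pi": s.pi,
                             "ka": s.ka, "ks": s.ks, "ka_ks": s.ka_ks,
                             "ka_ks_method": "NG86+JC", "deletion": "pairwise"})
            df = pd.DataFrame(rows)
            for col in ("mean_k2p", "pi", "ka", "ks", "ka_ks"):
                if col in df:
                    df[col] = df[col].map(
                        lambda v: round(v, 5) if isinstance(v, float) else v)
            emit("selection_table.tsv", df)
        except Exception:
            logger.exception("selection stage failed")

    if "cr" in cfg.stages:
        try:
            lib = cr.BoxLibrary.load()
            repeat_kwargs = dict(min_period=cfg.repeat_min_period,
                                 max_period=cfg.repeat_max_period,
                                 min_copies=cfg.repeat_min_copies,
                                 min_purity=cfg.repeat_min_purity)
            table, tracks = cr.cr_report(genomes, lib, cfg.identity_threshold,
                                         **repeat_kwargs)
            emit("cr_table.tsv", table)
            bed_path = outdir / "motif_tracks.bed"
            cr.write_bed(tracks, bed_path)
            written["motif_tracks.bed"] = bed_path
            seqs: dict[str, str] = {}
            for g in genomes:
                cr1, cr2 = cr.extract_cr_sequences(g)
                if cr1:
                    seqs[f"{g.id}_CR1"] = cr1
                if cr2:
                    seqs[f"{g.id}_CR2"] = cr2
            if len(seqs) >= 3:
                dm = sel.DistanceMatrix.from_sequences(seqs, model="TN93")
                tree_path = outdir / "cr_tree.nwk"
                tree_path.write_text(sel.nj_tree(dm) + "\n")
                written["cr_tree.nwk"] = tree_path
        except Exception:
            logger.exception("control-region stage failed")

    try:
        write_gene_order(genomes, outdir / "gene_order.tsv")
        written["gene_order.tsv"] = outdir / "gene_order.tsv"
    except Exception:
        logger.exception("gene-order output failed")

    manifest = {"source": source, "config_hash": cfg.config_hash,
                "config": dataclasses.asdict(cfg),
                "artifacts": sorted(written)}
    (outdir / "run_manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str) + "\n")
    written["run_manifest.json"] = outdir / "run_manifest.json"
    return written
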