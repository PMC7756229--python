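"""Readers and writers for the pipeline's on-disk formats.

Variant tables travel as a small VCF dialect (sites-only VCFv4.2 with
per-population called/count-based allele frequencies, total depth,
alternative-allele count, gene assignment and effect class in INFO); scan
statistics as TSV; gene models as GFF3 plus a spliced-CDS FASTA.
"""

from __future__ import annotations

from pathlib import Path
from typing import Dict, List, Sequence

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from cyvcf2 import VCF

from .genes import GeneModel

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=DP,Number=1,Type=Integer,Description="Total depth across population pools">
##INFO=<ID=AC,Number=1,Type=Integer,Description="Alternative allele count summed across pools">
##INFO=<ID=AF,Number=.,Type=Float,Description="Per-population alternative allele frequency (caller)">
##INFO=<ID=CF,Number=.,Type=Float,Description="Per-population alternative allele frequency (read counts)">
##INFO=<ID=GENE,Number=1,Type=String,Description="Containing gene (one-to-one ortholog ID)">
##INFO=<ID=EFF,Number=1,Type=String,Description="Predicted coding effect">
"""


def write_variant_file(table: pd.DataFrame, path) -> None:
    """Write a per-species variant table as a sites-only VCF.

    Expects the scan-table schema of :func:`convergescan.simulate.gen_scan_table`
    (at least chrom, pos, ref, alt, qual, coverage, alt_count, af_*/cf_*).
    """
    if len(table) == 0:
        raise ValueError("refusing to write an empty variant table")
    af_cols = [c for c in table.columns if c.startswith("af_")]
    cf_cols = [c for c in table.columns if c.startswith("cf_")]
    has_gene = "gene" in table.columns
    has_eff = "effect" in table.columns
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for chrom in pd.unique(table["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for row in table.itertuples(index=False):
            d = row._asdict()
            info = [f"DP={int(d['coverage'])}", f"AC={int(d['alt_count'])}"]
            if af_cols:
                info.append("AF=" + ",".join(f"{d[c]:.4f}" for c in af_cols))
            if cf_cols:
                info.append("CF=" + ",".join(f"{d[c]:.4f}" for c in cf_cols))
            if has_gene and pd.notna(d["gene"]):
                info.append(f"GENE={d['gene']}")
            if has_eff and pd.notna(d["effect"]):
                info.append(f"EFF={d['effect']}")
            fh.write(
                f"{d['chrom']}\t{int(d['pos'])}\t.\t{d['ref']}\t{d['alt']}\t"
                f"{d['qual']:.1f}\t.\t{';'.join(info)}\n"
            )


def read_variant_file(path, species: str) -> pd.DataFrame:
    """Read the VCF dialect back into the scan-table variant schema."""
    rows = []
    for v in VCF(str(path)):
        af = v.INFO.get("AF")
        cf = v.INFO.get("CF")
        af = (af,) if isinstance(af, float) else (af or ())
        cf = (cf,) if isinstance(cf, float) else (cf or ())
        rec = {
            "species": species,
            "chrom": v.CHROM,
            "pos": v.POS,
            "gene": v.INFO.get("GENE"),
            "ref": v.REF,
            "alt": ",".join(v.ALT),
            "qual": round(float(v.QUAL), 1),
            "coverage": v.INFO.get("DP"),
            "alt_count": v.INFO.get("AC"),
            "effect": v.INFO.get("EFF"),
        }
        for i, x in enumerate(af):
            rec[f"af_{i + 1}"] = round(float(x), 4)
        for i, x in enumerate(cf):
            rec[f"cf_{i + 1}"] = round(float(x), 4)
        rows.append(rec)
    df = pd.DataFrame(rows)
    if "gene" in df.columns:
        df["gene"] = df["gene"].astype(object).where(df["gene"].notna(), pd.NA)
    return df


def write_scan_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_scan_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_gene_models_gff(models: Sequence[GeneModel], path) -> None:
    """GFF3 with gene + CDS features; ortholog key in the gene's attributes."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for m in models:
            gid = f"gene:{m.gene_id}"
            fh.write(
                f"{m.chrom}\tconvergescan\tgene\t{m.start}\t{m.end}\t.\t{m.strand}\t.\t"
                f"ID={gid};ortholog={m.gene_id}\n"
            )
            segs = m.cds_segments if m.strand == "+" else m.cds_segments[::-1]
            phase = 0
            for s, e in segs:
                fh.write(
                    f"{m.chrom}\tconvergescan\tCDS\t{s}\t{e}\t.\t{m.strand}\t{phase}\t"
                    f"ID=cds:{m.gene_id};Parent={gid}\n"
                )
                phase = (3 - ((e - s + 1) - phase) % 3) % 3


def write_cds_fasta(models: Sequence[GeneModel], path) -> None:
    """Spliced coding-strand CDS sequences keyed by ortholog ID."""
    records = [
        SeqRecord(Seq(m.cds_sequence), id=m.gene_id, description="")
        for m in models
    ]
    SeqIO.write(records, str(path), "fasta")


def read_gene_models(gff_path, fasta_path, species: str) -> List[GeneModel]:
    """Rebuild gene models from GFF3 + CDS FASTA."""
    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    db = gffutils.create_db(
        str(gff_path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    models = []
    for gene in db.features_of_type("gene"):
        gene_id = gene.attributes["ortholog"][0]
        segs = tuple(
            sorted((c.start, c.end) for c in db.children(gene, featuretype="CDS"))
        )
        models.append(
            GeneModel(
                species=species,
                gene_id=gene_id,
                chrom=gene.seqid,
                start=gene.start,
                end=gene.end,
                strand=gene.strand,
                cds_segments=segs,
                cds_sequence=seqs[gene_id],
            )
        )
    return models
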