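"""Readers and writers for the pipeline's plain-text interchange formats.

Conventions: TSV/VCF coordinates are 1-based inclusive; BED intervals are
0-based half-open.  All tables round-trip losslessly through these
functions.
"""

from __future__ import annotations

import os
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SNP_TSV_COLUMNS = [
    "snp_id", "gene_id", "tumour_id", "region_id", "chrom", "pos",
    "phase_block_id", "dna_major_count", "dna_minor_count",
    "rna_major_count", "rna_minor_count", "major_cn", "minor_cn",
    "major_is_reference", "major_is_hap1",
]

VARIANT_INFO_FIELDS = [
    ("STRAND", "String", "Transcript strand of the variant"),
    ("C5", "String", "4-base genomic context 5prime of the variant"),
    ("C3", "String", "4-base genomic context 3prime of the variant"),
    ("RD", "Integer", "RNA read depth"),
    ("RA", "Integer", "RNA reads supporting the alternative base"),
    ("GD", "Integer", "Germline DNA depth"),
    ("TD", "Integer", "Total tumour DNA depth across regions"),
    ("AS", "Integer", "Tumour DNA reads supporting the alternative base"),
    ("ES", "Integer", "Tumour DNA reads supporting any other base"),
    ("REGION", "String", "Tumour region identifier"),
    ("TUMOUR", "String", "Tumour identifier"),
]


def write_snp_table(snps: pd.DataFrame, path) -> None:
    snps.to_csv(path, sep="\t", index=False, columns=[
        c for c in SNP_TSV_COLUMNS if c in snps.columns])


def read_snp_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_counts(counts: pd.DataFrame, path) -> None:
    counts.to_csv(path, sep="\t", index_label="gene_id")


def read_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="gene_id")


def write_region_meta(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_region_meta(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_bed(intervals: pd.DataFrame, path) -> None:
    intervals.to_csv(path, sep="\t", index=False, header=False)


def read_bed(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", header=None,
                       names=["chrom", "start", "end"],
                       usecols=[0, 1, 2])


def write_fasta(records: list[tuple[str, str]], path) -> None:
    SeqIO.write([SeqRecord(Seq(seq), id=name, description="")
                 for name, seq in records], str(path), "fasta")


def read_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


def write_strand_table(strands: pd.DataFrame, path) -> None:
    """Sidecar TSV mapping transcript -> strand ('+'/'-')."""
    strands.to_csv(path, sep="\t", index=False)


def read_strand_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# candidate-variant VCF (v4.2)
# ---------------------------------------------------------------------------

def write_variants_vcf(variants: pd.DataFrame, path,
                       contig_lengths: dict[str, int] | None = None) -> None:
    """Write a candidate RNA-variant table as a VCF v4.2 with the depth and
    context annotations the filter stage consumes stored as INFO fields."""
    lines = ["##fileformat=VCFv4.2", "##source=txevo"]
    if contig_lengths:
        for name, length in contig_lengths.items():
            lines.append(f"##contig=<ID={name},length={length}>")
    for key, typ, desc in VARIANT_INFO_FIELDS:
        lines.append(f'##INFO=<ID={key},Number=1,Type={typ},Description="{desc}">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    ordered = variants.sort_values(["chrom", "pos"], kind="stable")
    for _, v in ordered.iterrows():
        info = ";".join([
            f"STRAND={v['transcript_strand']}", f"C5={v['context5']}",
            f"C3={v['context3']}", f"RD={int(v['rna_depth'])}",
            f"RA={int(v['rna_alt'])}", f"GD={int(v['dna_germline_depth'])}",
            f"TD={int(v['dna_tumour_depth_total'])}",
            f"AS={int(v['dna_alt_support'])}",
            f"ES={int(v['dna_error_support'])}",
            f"REGION={v['region_id']}", f"TUMOUR={v['tumour_id']}",
        ])
        lines.append(f"{v['chrom']}\t{int(v['pos'])}\t.\t{v['ref']}\t{v['alt']}"
                     f"\t.\t.\t{info}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_variants_vcf(path) -> pd.DataFrame:
    """Read a candidate-variant VCF (via pysam) back into the filter-stage
    table, including the 1-base contexts derived from the 4-base flanks."""
    import pysam

    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            info = rec.info
            c5, c3 = str(info["C5"]), str(info["C3"])
            rows.append({
                "chrom": rec.chrom, "pos": rec.pos, "ref": rec.ref,
                "alt": rec.alts[0], "transcript_strand": str(info["STRAND"]),
                "context5": c5, "context3": c3, "up": c5[-1], "down": c3[0],
                "rna_depth": int(info["RD"]), "rna_alt": int(info["RA"]),
                "dna_germline_depth": int(info["GD"]),
                "dna_tumour_depth_total": int(info["TD"]),
                "dna_alt_support": int(info["AS"]),
                "dna_error_support": int(info["ES"]),
                "region_id": str(info["REGION"]),
                "tumour_id": str(info["TUMOUR"]),
            })
    return pd.DataFrame(rows)


def ensure_dir(path) -> Path:
    p = Path(path)
    os.makedirs(p, exist_ok=True)
    return p
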