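"""Readers and writers for the package's on-disk formats.

Cohorts are exchanged as a VCF v4.2 (haploid consensus GT plus a
per-sample AF FORMAT field carrying the within-host derived-allele
frequency), a TSV sample table and a TSV locus-annotation table.  All
writers emit UTF-8 with LF line endings and no timestamps, so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import os
from pathlib import Path

import numpy as np
import pandas as pd
import pysam

from .containers import GenotypeMatrix, LOCUS_COLUMNS
from .synth import GENOME_LENGTH

__all__ = [
    "write_fixtures", "write_sample_table", "read_sample_table",
    "write_genotype_vcf", "read_genotype_vcf", "write_loci_table",
    "read_loci_table", "write_mk_counts", "read_mk_counts",
]

_CONTIG = "DiNV"
_AF_DECIMALS = 4


def write_sample_table(samples: pd.DataFrame, path) -> Path:
    path = Path(path)
    samples.to_csv(path, sep="\t", index=False, lineterminator="\n",
                   float_format="%.6g", na_rep="NA")
    return path


def read_sample_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA"],
                     dtype={"sample_id": str, "population": str})
    if "infected" in df.columns:
        df["infected"] = df["infected"].astype(bool)
    if "wolbachia" in df.columns:
        df["wolbachia"] = df["wolbachia"].astype(bool)
    return df


def write_loci_table(loci: pd.DataFrame, path) -> Path:
    path = Path(path)
    loci.to_csv(path, sep="\t", lineterminator="\n", na_rep="NA")
    return path


def read_loci_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col="locus_id", na_values=["NA"])
    df["focal"] = df["focal"].astype(bool)
    return df


def _vcf_header(sample_ids) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(_CONTIG, length=GENOME_LENGTH)
    header.add_meta("INFO", items=[("ID", "ANN"), ("Number", "1"),
                                   ("Type", "String"),
                                   ("Description", "Annotation class")])
    header.add_meta("INFO", items=[("ID", "GENE"), ("Number", "1"),
                                   ("Type", "String"),
                                   ("Description", "Nearest gene")])
    header.add_meta("INFO", items=[("ID", "FOCAL"), ("Number", "0"),
                                   ("Type", "Flag"),
                                   ("Description", "Focal haplotype SNP")])
    header.add_meta("INFO", items=[("ID", "ORDER"), ("Number", "1"),
                                   ("Type", "Integer"),
                                   ("Description", "Focal mutation order index")])
    header.add_meta("FORMAT", items=[("ID", "GT"), ("Number", "1"),
                                     ("Type", "String"),
                                     ("Description", "Haploid consensus genotype")])
    header.add_meta("FORMAT", items=[("ID", "AF"), ("Number", "1"),
                                     ("Type", "Float"),
                                     ("Description",
                                      "Within-host derived allele frequency")])
    for s in sample_ids:
        header.add_sample(str(s))
    return header


def write_genotype_vcf(matrix: GenotypeMatrix, path) -> Path:
    path = Path(path)
    sample_ids = list(matrix.freq.index)
    header = _vcf_header(sample_ids)
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for locus_id, meta in matrix.loci.iterrows():
            rec = vcf.new_record(
                contig=_CONTIG, start=int(meta["position"]) - 1,
                stop=int(meta["position"]), alleles=("A", "T"), id=str(locus_id))
            rec.info["ANN"] = str(meta["annotation"])
            rec.info["GENE"] = str(meta["gene"])
            if bool(meta.get("focal", False)):
                rec.info["FOCAL"] = True
                order = meta.get("focal_order")
                if pd.notna(order):
                    rec.info["ORDER"] = int(order)
            col = matrix.freq[locus_id]
            for s in sample_ids:
                f = round(float(col.loc[s]), _AF_DECIMALS)
                rec.samples[str(s)]["GT"] = (1,) if f >= 0.5 else (0,)
                rec.samples[str(s)]["AF"] = f
            vcf.write(rec)
    return path


def read_genotype_vcf(path) -> GenotypeMatrix:
    loci_rows = []
    columns = []
    with pysam.VariantFile(str(path)) as vcf:
        sample_ids = list(vcf.header.samples)
        for rec in vcf:
            loci_rows.append({
                "locus_id": rec.id,
                "position": rec.pos,
                "annotation": rec.info.get("ANN", "intergenic"),
                "gene": rec.info.get("GENE", ""),
                "focal": bool(rec.info.get("FOCAL", False)),
                "focal_order": float(rec.info["ORDER"]) if "ORDER" in rec.info else np.nan,
            })
            columns.append([round(float(rec.samples[s]["AF"]), _AF_DECIMALS)
                            for s in sample_ids])
    loci = pd.DataFrame(
        loci_rows,
        columns=["locus_id", "position", "annotation", "gene", "focal", "focal_order"],
    ).set_index("locus_id")
    loci["focal"] = loci["focal"].astype(bool)
    if columns:
        freq = pd.DataFrame(np.array(columns).T,
                            index=pd.Index(sample_ids, name="sample_id"),
                            columns=loci.index)
    else:
        freq = pd.DataFrame(index=pd.Index(sample_ids, name="sample_id"))
    return GenotypeMatrix(freq=freq, loci=loci)


def write_fixtures(samples: pd.DataFrame, matrix: GenotypeMatrix, out_dir) -> dict:
    """Write the three cohort files; reading back reproduces the matrices."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "samples": write_sample_table(samples, out_dir / "samples.tsv"),
        "vcf": write_genotype_vcf(matrix, out_dir / "genotypes.vcf"),
        "loci": write_loci_table(matrix.loci, out_dir / "loci.tsv"),
    }
    return paths


def write_mk_counts(counts: pd.DataFrame, path) -> Path:
    path = Path(path)
    counts.to_csv(path, sep="\t", index=False, lineterminator="\n", na_rep="NA")
    return path


def read_mk_counts(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["NA"])
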