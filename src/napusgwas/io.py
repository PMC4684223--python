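"""Readers and writers for the pipeline's standard formats.

Genotypes travel as a samples x markers TSV of minor-allele dosages
(missing = ``NA``), minimal GT-only VCF 4.2, or PLINK-style .ped/.map
text.  Phenotypes are long-format TSV (accession, trait, env, rep,
value).  Gene models are GFF3 (read through :mod:`gffutils`).  All
coordinates are 1-based inclusive.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeMatrix, validate_marker_map

# ---------------------------------------------------------------------------
# genotype TSV
# ---------------------------------------------------------------------------


def write_genotype_tsv(G: GenotypeMatrix, marker_map: pd.DataFrame, path) -> None:
    """Samples x markers dosage TSV; header row carries marker ids."""
    df = pd.DataFrame(G.dosages, index=G.samples, columns=marker_map["id"])
    df = df.replace(MISSING, np.nan)
    df.to_csv(path, sep="\t", index_label="sample", na_rep="NA", float_format="%.0f")


def read_genotype_tsv(path) -> tuple[GenotypeMatrix, list[str]]:
    """Read a dosage TSV; returns the matrix and the header marker ids."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    dos = df.to_numpy(dtype=float)
    dos = np.where(np.isnan(dos), MISSING, dos).astype(np.int8)
    return GenotypeMatrix(dos, df.index.to_numpy(dtype=object)), list(df.columns)


def write_marker_map(marker_map: pd.DataFrame, path) -> None:
    marker_map.to_csv(path, sep="\t", index=False)


def read_marker_map(path) -> pd.DataFrame:
    mm = pd.read_csv(path, sep="\t")
    validate_marker_map(mm)
    return mm


# ---------------------------------------------------------------------------
# VCF 4.2
# ---------------------------------------------------------------------------


def write_vcf(G: GenotypeMatrix, marker_map: pd.DataFrame, path) -> None:
    """Minimal biallelic GT-only VCF 4.2; REF = major allele, ALT = minor."""
    gt_strings = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in pd.unique(marker_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(map(str, G.samples)) + "\n")
        for j, row in enumerate(marker_map.itertuples(index=False)):
            calls = "\t".join(gt_strings[int(d)] for d in G.dosages[:, j])
            fh.write(
                f"{row.chrom}\t{row.pos}\t{row.id}\t{row.major_allele}\t"
                f"{row.minor_allele}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read biallelic SNPs from a VCF (GT field); multi-allelic records skipped."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    rows, dosage_cols = [], []
    n_skipped = 0
    for var in vcf:
        if len(var.ALT) != 1 or len(var.REF) != 1 or len(var.ALT[0]) != 1:
            n_skipped += 1
            continue
        gts = np.asarray(var.genotypes, dtype=object)
        dose = np.empty(len(samples), dtype=np.int8)
        for i, gt in enumerate(gts):
            a, b = gt[0], gt[1]
            dose[i] = MISSING if (a < 0 or b < 0) else a + b
        dosage_cols.append(dose)
        rows.append(
            {
                "id": var.ID or f"{var.CHROM}_{var.POS}",
                "chrom": var.CHROM,
                "pos": var.POS,
                "major_allele": var.REF,
                "minor_allele": var.ALT[0],
            }
        )
    vcf.close()
    if n_skipped:
        warnings.warn(f"skipped {n_skipped} non-biallelic-SNP records", stacklevel=2)
    mm = pd.DataFrame(rows)
    G = GenotypeMatrix(np.column_stack(dosage_cols) if dosage_cols else np.empty((len(samples), 0), np.int8), samples)
    return G, mm


# ---------------------------------------------------------------------------
# PLINK text (.ped / .map)
# ---------------------------------------------------------------------------


def write_plink(G: GenotypeMatrix, marker_map: pd.DataFrame, prefix) -> None:
    """PLINK-style text files: ``<prefix>.map`` (chrom, id, 0, bp) and
    ``<prefix>.ped`` with two allele columns per marker ('0 0' = missing)."""
    prefix = str(prefix)
    marker_map.assign(cm=0)[["chrom", "id", "cm", "pos"]].to_csv(
        f"{prefix}.map", sep="\t", header=False, index=False
    )
    major = marker_map["major_allele"].to_numpy()
    minor = marker_map["minor_allele"].to_numpy()
    with open(f"{prefix}.ped", "w") as fh:
        for i, sample in enumerate(G.samples):
            fields = [str(sample), str(sample), "0", "0", "0", "-9"]
            dos = G.dosages[i]
            for j, d in enumerate(dos):
                if d == MISSING:
                    fields += ["0", "0"]
                elif d == 0:
                    fields += [major[j], major[j]]
                elif d == 1:
                    fields += [major[j], minor[j]]
                else:
                    fields += [minor[j], minor[j]]
            fh.write(" ".join(fields) + "\n")


def read_plink(prefix) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Read PLINK .ped/.map text; dosages count the minor (rarer) allele."""
    prefix = str(prefix)
    mm = pd.read_csv(
        f"{prefix}.map", sep=r"\s+", header=None, names=["chrom", "id", "cm", "pos"]
    )
    samples, rows = [], []
    with open(f"{prefix}.ped") as fh:
        for line in fh:
            parts = line.split()
            samples.append(parts[1])
            rows.append(parts[6:])
    alleles = np.asarray(rows, dtype=object).reshape(len(samples), len(mm), 2)
    m = len(mm)
    dos = np.empty((len(samples), m), dtype=np.int8)
    majors, minors = [], []
    for j in range(m):
        a = alleles[:, j, :].ravel()
        obs = a[a != "0"]
        uniq, counts = np.unique(obs, return_counts=True)
        if uniq.size == 0:
            majors.append("N")
            minors.append("N")
            dos[:, j] = MISSING
            continue
        order = np.argsort(-counts, kind="stable")
        major = uniq[order[0]]
        minor = uniq[order[1]] if uniq.size > 1 else "N"
        majors.append(major)
        minors.append(minor)
        pair = alleles[:, j, :]
        miss = (pair == "0").any(axis=1)
        dos[:, j] = (pair == minor).sum(axis=1).astype(np.int8)
        dos[miss, j] = MISSING
    mm = mm.assign(major_allele=majors, minor_allele=minors)[
        ["id", "chrom", "pos", "major_allele", "minor_allele"]
    ]
    return GenotypeMatrix(dos, np.asarray(samples, dtype=object)), mm


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

PHENO_COLUMNS = ["accession", "trait", "env", "rep", "value"]


def write_phenotype_tsv(table: pd.DataFrame, path) -> None:
    table[PHENO_COLUMNS].to_csv(path, sep="\t", index=False)


def read_phenotype_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file {path}: missing columns {missing}")
    return df


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------


def write_gff3(annotation: pd.DataFrame, path) -> None:
    """Gene features only; 1-based inclusive coordinates per the standard."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for row in annotation.itertuples(index=False):
            fh.write(
                f"{row.chrom}\tnapusgwas\tgene\t{row.start}\t{row.end}\t.\t"
                f"{row.strand}\t.\tID={row.gene_id}\n"
            )


def read_gff3(path) -> pd.DataFrame:
    """Gene features from a GFF3 file as a sorted annotation DataFrame."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    rows = [
        {
            "gene_id": g.id,
            "chrom": g.seqid,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
        }
        for g in db.features_of_type("gene")
    ]
    return (
        pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])
        .sort_values(["chrom", "start"], kind="stable")
        .reset_index(drop=True)
    )


# ---------------------------------------------------------------------------
# matrices and metadata
# ---------------------------------------------------------------------------


def write_matrix_tsv(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index_label="sample")


def read_matrix_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_metadata(meta: dict, path) -> None:
    Path(path).write_text(json.dumps(meta, indent=2, default=str) + "\n")


def read_metadata(path) -> dict:
    return json.loads(Path(path).read_text())
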