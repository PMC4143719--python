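"""Readers and writers for genotype and phenotype files.

Genotypes travel as VCF 4.2 (unphased GT, ``./.`` for missing; ALT is the
internally counted allele) or as a PLINK-style PED/MAP text pair (``0 0``
for missing). Reading a file written by this module reproduces the genotype
matrix exactly. Phenotypes are two CSVs: one row per individual-exam and
one row per individual; empty fields or ``NA`` mark missing values.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .containers import MISSING, GenotypeMatrix

# ---------------------------------------------------------------------------
# VCF


def write_vcf(G: GenotypeMatrix, path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for chrom in G.snps["chrom"].unique():
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(G.individuals)
            + "\n"
        )
        gt_map = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
        for j in range(G.n_snps):
            snp = G.snps.iloc[j]
            calls = "\t".join(gt_map[int(v)] for v in G.values[:, j])
            fh.write(
                f"{snp['chrom']}\t{snp['pos']}\t{snp['id']}\t{snp['major_allele']}\t"
                f"{snp['minor_allele']}\t.\tPASS\t.\tGT\t{calls}\n"
            )


def read_vcf(path) -> GenotypeMatrix:
    """Read a VCF; genotype values count copies of the (first) ALT allele."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    individuals = list(vcf.samples)
    rows = []
    cols = []
    for var in vcf:
        alt = var.ALT[0] if var.ALT else "."
        rows.append(
            {
                "id": var.ID or f"{var.CHROM}:{var.POS}",
                "chrom": str(var.CHROM),
                "pos": int(var.POS),
                "minor_allele": alt,
                "major_allele": var.REF,
            }
        )
        col = np.empty(len(individuals), dtype=np.int8)
        for i, g in enumerate(var.genotypes):
            a, b = g[0], g[1]
            col[i] = MISSING if (a < 0 or b < 0) else (a > 0) + (b > 0)
        cols.append(col)
    vcf.close()
    values = (
        np.column_stack(cols) if cols else np.zeros((len(individuals), 0), dtype=np.int8)
    )
    return GenotypeMatrix(values, pd.DataFrame(rows), individuals)


# ---------------------------------------------------------------------------
# PED/MAP


def write_ped(G: GenotypeMatrix, prefix) -> None:
    """PED/MAP pair at ``prefix + '.ped'`` / ``'.map'``; missing = ``0 0``.

    PED/MAP does not record which allele the genotype values count, so a
    sidecar ``<prefix>.alleles.tsv`` (snp id, counted allele, other allele)
    is written alongside; :func:`read_ped` uses it when present to restore
    allele roles exactly, and otherwise falls back to a rarer-allele
    heuristic.
    """
    prefix = Path(prefix)
    with prefix.with_suffix(".map").open("w") as fh:
        for j in range(G.n_snps):
            snp = G.snps.iloc[j]
            fh.write(f"{snp['chrom']}\t{snp['id']}\t0\t{snp['pos']}\n")
    with prefix.with_suffix(".alleles.tsv").open("w") as fh:
        fh.write("id\tminor_allele\tmajor_allele\n")
        for j in range(G.n_snps):
            snp = G.snps.iloc[j]
            fh.write(f"{snp['id']}\t{snp['minor_allele']}\t{snp['major_allele']}\n")
    minor = G.snps["minor_allele"].to_numpy()
    major = G.snps["major_allele"].to_numpy()
    with prefix.with_suffix(".ped").open("w") as fh:
        for i, iid in enumerate(G.individuals):
            fields = [iid, iid, "0", "0", "0", "-9"]
            for j, v in enumerate(G.values[i]):
                if v == MISSING:
                    fields += ["0", "0"]
                elif v == 0:
                    fields += [major[j], major[j]]
                elif v == 1:
                    fields += [major[j], minor[j]]
                else:
                    fields += [minor[j], minor[j]]
            fh.write(" ".join(fields) + "\n")


def read_ped(prefix) -> GenotypeMatrix:
    """Read a PED/MAP pair; genotype values count the ``minor_allele``.

    Allele roles come from the ``<prefix>.alleles.tsv`` sidecar when
    present (exact round trip); otherwise the rarer observed allele is
    taken as minor, ties broken alphabetically.
    """
    prefix = Path(prefix)
    sidecar = prefix.with_suffix(".alleles.tsv")
    roles: dict[str, tuple[str, str]] = {}
    if sidecar.exists():
        side = pd.read_csv(sidecar, sep="\t", dtype=str)
        roles = {
            r.id: (r.minor_allele, r.major_allele) for r in side.itertuples(index=False)
        }
    snp_rows = []
    with prefix.with_suffix(".map").open() as fh:
        for line in fh:
            chrom, sid, _, pos = line.split()
            snp_rows.append({"id": sid, "chrom": chrom, "pos": int(pos)})
    m = len(snp_rows)
    individuals = []
    allele_rows = []
    with prefix.with_suffix(".ped").open() as fh:
        for line in fh:
            parts = line.split()
            individuals.append(parts[1])
            alleles = parts[6:]
            if len(alleles) != 2 * m:
                raise ValueError("PED row length does not match MAP")
            allele_rows.append(alleles)
    values = np.empty((len(individuals), m), dtype=np.int8)
    for j in range(m):
        if snp_rows[j]["id"] in roles:
            minor, major = roles[snp_rows[j]["id"]]
        else:
            counts: dict[str, int] = {}
            for row in allele_rows:
                for a in (row[2 * j], row[2 * j + 1]):
                    if a != "0":
                        counts[a] = counts.get(a, 0) + 1
            alleles_sorted = sorted(counts.items(), key=lambda kv: (kv[1], kv[0]))
            if not alleles_sorted:
                minor, major = "A", "G"
            elif len(alleles_sorted) == 1:
                minor, major = "?", alleles_sorted[0][0]
            else:
                minor, major = alleles_sorted[0][0], alleles_sorted[-1][0]
        snp_rows[j]["minor_allele"] = minor
        snp_rows[j]["major_allele"] = major
        for i, row in enumerate(allele_rows):
            a, b = row[2 * j], row[2 * j + 1]
            if a == "0" or b == "0":
                values[i, j] = MISSING
            else:
                values[i, j] = (a == minor) + (b == minor)
    return GenotypeMatrix(values, pd.DataFrame(snp_rows), individuals)


# ---------------------------------------------------------------------------
# Phenotype CSVs


def write_phenotypes(exam_df: pd.DataFrame, subject_df: pd.DataFrame, exam_path, subject_path) -> None:
    exam_df.to_csv(exam_path, index=False)
    subject_df.to_csv(subject_path, index=False)


def read_exam_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA", ""])
    need = {"individual_id", "exam", "sbp", "dbp", "meds", "smokes"}
    if not need <= set(df.columns):
        raise ValueError(f"exam CSV lacks columns {sorted(need - set(df.columns))}")
    df["individual_id"] = df["individual_id"].astype(str)
    return df


def read_subject_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path, na_values=["NA", ""])
    need = {"individual_id", "sex", "age"}
    if not need <= set(df.columns):
        raise ValueError(f"subject CSV lacks columns {sorted(need - set(df.columns))}")
    df["individual_id"] = df["individual_id"].astype(str)
    return df


def write_dataset(sim, fmt: str, outdir) -> dict[str, Path]:
    """Write a simulated dataset (genotypes + phenotype CSVs + truth tables)."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    if fmt == "vcf":
        paths["genotypes"] = outdir / "genotypes.vcf"
        write_vcf(sim.genotypes, paths["genotypes"])
    elif fmt == "ped":
        paths["genotypes"] = outdir / "genotypes.ped"
        write_ped(sim.genotypes, outdir / "genotypes")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    paths["exams"] = outdir / "exams.csv"
    paths["subjects"] = outdir / "subjects.csv"
    write_phenotypes(sim.exam_df, sim.subject_df, paths["exams"], paths["subjects"])
    truth_dip = []
    for bi, dips in sim.true_diplotypes.items():
        for iid, (a, b) in zip(sim.genotypes.individuals, dips):
            truth_dip.append({"individual_id": iid, "block": bi, "hap1": a, "hap2": b})
    paths["true_diplotypes"] = outdir / "true_diplotypes.csv"
    pd.DataFrame(truth_dip).to_csv(paths["true_diplotypes"], index=False)
    paths["truth"] = outdir / "truth.csv"
    sim.truth.to_csv(paths["truth"], index=False)
    return paths
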