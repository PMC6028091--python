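"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as a minimal VCF (GT only) or a dosage TSV (SNP rows,
sample columns); gene maps as 6-column BED (0-based half-open, converted
from the 1-based inclusive internal convention at this boundary only);
phenotypes, association results, QC reports and GRMs as TSV.  All numeric
output uses a fixed "%.10g" format so repeated runs are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .simdata import GeneMap, GenotypePanel, TraitTable, TRAIT_ROLES

FLOAT_FMT = "%.10g"
_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(panel: GenotypePanel, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=awmpcit-simdata\n")
        if panel.chrom_lengths:
            for c in sorted(panel.chrom_lengths):
                fh.write(f"##contig=<ID={c},length={panel.chrom_lengths[c]}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(panel.sample_ids) + "\n")
        for j in range(panel.n_snps):
            gts = "\t".join(_GT[int(g)] for g in panel.dosage[:, j])
            fh.write(f"{panel.chrom[j]}\t{panel.pos[j]}\t{panel.snp_ids[j]}\t"
                     f"{panel.ref_allele}\t{panel.alt_allele}\t.\tPASS\t.\tGT\t{gts}\n")


def read_vcf(path: str | Path, breed_of: dict[str, str] | None = None) -> GenotypePanel:
    """Read a VCF into a GenotypePanel (ALT-allele dosage from GT).

    ``breed_of`` maps sample id to breed label; samples default to breed A.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.array(vcf.samples)
    chroms, poss, ids, rows = [], [], [], []
    for var in vcf:
        chroms.append(int(var.CHROM))
        poss.append(var.POS)
        ids.append(var.ID or f"snp{var.CHROM}_{var.POS}")
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        rows.append(np.array([0, 1, -1, 2], dtype=np.int8)[var.gt_types])
    vcf.close()
    dosage = np.array(rows, dtype=np.int8).T if rows else np.empty((len(samples), 0), np.int8)
    breed = np.array([(breed_of or {}).get(s, "A") for s in samples])
    breeds = tuple(sorted(set(breed)))
    panel = GenotypePanel(
        sample_ids=samples, breed=breed,
        snp_ids=np.array(ids), chrom=np.array(chroms, dtype=np.int64),
        pos=np.array(poss, dtype=np.int64), dosage=dosage,
        breeds=breeds, allele_freq=np.empty((len(breeds), len(ids))),
    )
    panel.allele_freq = panel.observed_freq()
    return panel


def write_dosage_tsv(panel: GenotypePanel, geno_path: str | Path,
                     samples_path: str | Path) -> None:
    df = pd.DataFrame(panel.dosage.T, index=pd.Index(panel.snp_ids, name="snp_id"),
                      columns=panel.sample_ids)
    df.insert(0, "chrom", panel.chrom)
    df.insert(1, "pos", panel.pos)
    df.to_csv(geno_path, sep="\t")
    pd.DataFrame({"sample_id": panel.sample_ids, "breed": panel.breed}).to_csv(
        samples_path, sep="\t", index=False
    )


def read_dosage_tsv(geno_path: str | Path, samples_path: str | Path) -> GenotypePanel:
    geno = pd.read_csv(geno_path, sep="\t", index_col="snp_id")
    samples = pd.read_csv(samples_path, sep="\t")
    sample_ids = samples["sample_id"].to_numpy(dtype=str)
    breed = samples["breed"].to_numpy(dtype=str)
    dosage = geno[sample_ids].to_numpy(dtype=np.int8).T
    breeds = tuple(dict.fromkeys(breed))  # preserve file order
    panel = GenotypePanel(
        sample_ids=sample_ids, breed=breed,
        snp_ids=geno.index.to_numpy(dtype=str),
        chrom=geno["chrom"].to_numpy(dtype=np.int64),
        pos=geno["pos"].to_numpy(dtype=np.int64),
        dosage=dosage, breeds=breeds,
        allele_freq=np.empty((len(breeds), len(geno))),
    )
    panel.allele_freq = panel.observed_freq()
    return panel


def write_bed(genes: GeneMap, path: str | Path) -> None:
    """6-column BED; internal 1-based inclusive -> 0-based half-open."""
    with open(path, "w") as fh:
        for i in range(genes.n_genes):
            fh.write(f"{genes.chrom[i]}\t{genes.start[i] - 1}\t{genes.end[i]}\t"
                     f"{genes.gene_ids[i]}\t0\t{genes.strand[i]}\n")


def read_bed(path: str | Path,
             chrom_lengths: dict[int, int] | None = None) -> GeneMap:
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith(("track", "browser", "#")):
                continue
            f = line.rstrip("\n").split("\t")
            rows.append((int(f[0]), int(f[1]) + 1, int(f[2]), f[3],
                         f[5] if len(f) > 5 else "+"))
    rows.sort(key=lambda r: (r[0], r[1]))
    gm = GeneMap(
        gene_ids=np.array([r[3] for r in rows]),
        chrom=np.array([r[0] for r in rows], dtype=np.int64),
        start=np.array([r[1] for r in rows], dtype=np.int64),
        end=np.array([r[2] for r in rows], dtype=np.int64),
        strand=np.array([r[4] for r in rows]),
        chrom_lengths=chrom_lengths,
    )
    gm.validate()
    return gm


def write_phenotypes(traits: TraitTable, path: str | Path) -> None:
    df = traits.values.copy()
    df.insert(0, "breed", traits.breed)
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT)


def read_phenotypes(path: str | Path) -> TraitTable:
    df = pd.read_csv(path, sep="\t", index_col="sample_id")
    breed = df.pop("breed").to_numpy(dtype=str)
    return TraitTable(sample_ids=df.index.to_numpy(dtype=str), breed=breed,
                      values=df.astype(float), trait_role=dict(TRAIT_ROLES))


def write_table(df: pd.DataFrame, path: str | Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=FLOAT_FMT, index=index)


def write_grm(sample_ids: np.ndarray, matrix: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(matrix, index=sample_ids, columns=sample_ids).to_csv(
        path, sep="\t", float_format=FLOAT_FMT
    )
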