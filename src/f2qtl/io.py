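"""Plain-text dataset I/O: PLINK PED/MAP, VCF 4.2, phenotype/pedigree tables.

Only markers (biallelic) go into PED/VCF; QTL genotypes are exported as a
tagged TSV. Map positions are cM; the VCF encodes them as integer pseudo-bp
at 1 cM = 1e6 bp. Missing genotypes are "0 0" (PED) / "./." (VCF).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .forward_sim import Population, UNKNOWN_PARENT
from .genome import GenomeMap
from .quantgen import MISSING, TraitArchitecture

__all__ = [
    "write_ped_map", "read_ped_map",
    "write_vcf", "read_vcf",
    "write_phenotypes", "read_phenotypes",
    "write_pedigree", "write_qtl_genotypes", "write_trait_architecture",
]

CM_TO_BP = 1_000_000
_PED_CODE = {0: "1 1", 1: "1 2", 2: "2 2", MISSING: "0 0"}


def _marker_meta(genome: GenomeMap):
    idx = genome.marker_idx
    return genome.chrom[idx], genome.pos[idx], genome.ids[idx]


def write_ped_map(path_prefix: str, pop: Population, genome: GenomeMap,
                  observed: np.ndarray | None = None) -> None:
    """Write <prefix>.ped / <prefix>.map for the panel markers.

    *observed* is an (n, M) matrix with -1 for missing; defaults to the true
    genotypes.
    """
    chrom, pos, ids = _marker_meta(genome)
    geno = pop.marker_genotypes(genome) if observed is None else observed
    with open(f"{path_prefix}.map", "w") as fh:
        for c, p, i in zip(chrom, pos, ids):
            fh.write(f"{c + 1}\t{i}\t{p:.10g}\t{int(round(p * CM_TO_BP))}\n")
    pheno = pop.phenotype
    with open(f"{path_prefix}.ped", "w") as fh:
        for r in range(pop.n):
            ph = "-9" if pheno is None else f"{pheno[r]:.6g}"
            head = (f"{pop.label} {pop.ids[r]} {pop.sire[r]} {pop.dam[r]} "
                    f"{pop.sex[r]} {ph}")
            body = " ".join(_PED_CODE[int(g)] for g in geno[r])
            fh.write(head + " " + body + "\n")


def read_ped_map(path_prefix: str):
    """Read PED/MAP back: (genotypes with -1 missing, marker meta dataframe,
    sample dataframe)."""
    mp = pd.read_csv(f"{path_prefix}.map", sep="\t", header=None,
                     names=["chrom", "id", "pos_cM", "bp"])
    samples, rows = [], []
    with open(f"{path_prefix}.ped") as fh:
        for line in fh:
            f = line.split()
            samples.append(f[:6])
            al = np.array(f[6:], dtype=np.int8).reshape(-1, 2)
            g = (al - 1).sum(axis=1).astype(np.int8)
            g[(al == 0).any(axis=1)] = MISSING
            rows.append(g)
    geno = np.vstack(rows)
    sdf = pd.DataFrame(samples, columns=["fid", "iid", "sire", "dam", "sex", "phenotype"])
    return geno, mp, sdf


def write_vcf(path: str, pop: Population, genome: GenomeMap,
              observed: np.ndarray | None = None) -> None:
    """Minimal VCF 4.2 with GT fields for the panel markers (REF=A, ALT=B)."""
    chrom, pos, ids = _marker_meta(genome)
    geno = pop.marker_genotypes(genome) if observed is None else observed
    gt = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=f2qtl\n")
        for c, L in enumerate(genome.chrom_lengths):
            fh.write(f"##contig=<ID={c + 1},length={int(L * CM_TO_BP) + 1}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(str(s) for s in pop.ids) + "\n")
        for j in range(len(ids)):
            cells = "\t".join(gt[int(g)] for g in geno[:, j])
            fh.write(f"{chrom[j] + 1}\t{int(round(pos[j] * CM_TO_BP))}\t{ids[j]}"
                     f"\tA\tB\t.\tPASS\t.\tGT\t{cells}\n")


def read_vcf(path: str):
    """Read a VCF into (genotypes with -1 missing, marker meta dataframe,
    sample ids) via cyvcf2."""
    from cyvcf2 import VCF

    v = VCF(path)
    samples = list(v.samples)
    rows, meta = [], []
    for rec in v:
        g = rec.genotype.array()[:, :2]
        col = g.sum(axis=1).astype(np.int8)
        col[(g < 0).any(axis=1)] = MISSING
        rows.append(col)
        meta.append((int(rec.CHROM), rec.ID, rec.POS / CM_TO_BP))
    geno = np.vstack(rows).T
    mdf = pd.DataFrame(meta, columns=["chrom", "id", "pos_cM"])
    return geno, mdf, samples


def write_phenotypes(path: str, pop: Population) -> None:
    pd.DataFrame({
        "id": pop.ids,
        "generation": pop.generation,
        "sex": pop.sex,
        "phenotype": pop.phenotype if pop.phenotype is not None else np.nan,
        "tbv": pop.tbv if pop.tbv is not None else np.nan,
    }).to_csv(path, sep="\t", index=False)


def read_phenotypes(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_pedigree(path: str, pop: Population) -> None:
    """CSV pedigree; unknown parents written as "0"."""
    pd.DataFrame({
        "id": pop.ids,
        "sire": [s if s != UNKNOWN_PARENT else "0" for s in pop.sire],
        "dam": [d if d != UNKNOWN_PARENT else "0" for d in pop.dam],
        "sex": pop.sex,
        "generation": pop.generation,
        "population": pop.label,
        "tbv": pop.tbv if pop.tbv is not None else np.nan,
        "phenotype": pop.phenotype if pop.phenotype is not None else np.nan,
    }).to_csv(path, index=False)


def write_qtl_genotypes(path: str, pop: Population, genome: GenomeMap) -> None:
    """Tagged TSV of QTL allele pairs (one row per individual x QTL)."""
    al = pop.qtl_alleles(genome)
    qids = genome.ids[genome.qtl_idx]
    with open(path, "w") as fh:
        fh.write("id\tqtl\tallele_pat\tallele_mat\n")
        for r in range(pop.n):
            for j, q in enumerate(qids):
                fh.write(f"{pop.ids[r]}\t{q}\t{al[r, 0, j]}\t{al[r, 1, j]}\n")


def write_trait_architecture(path: str, trait: TraitArchitecture,
                             genome: GenomeMap) -> None:
    qidx = genome.qtl_idx
    with open(path, "w") as fh:
        fh.write("qtl\tchrom\tpos_cM\tallele\teffect\n")
        for j, gi in enumerate(qidx):
            for a in range(int(trait.allele_counts[j])):
                fh.write(f"{genome.ids[gi]}\t{genome.chrom[gi] + 1}\t"
                         f"{genome.pos[gi]:.10g}\t{a}\t"
                         f"{trait.allele_effects[j, a]:.10g}\n")
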