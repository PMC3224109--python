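"""Reading and writing genotype data.

Internally genotypes live in an individuals x SNPs int8 matrix with
additive minor-allele counts (0/1/2) and -1 as the missing sentinel.
The PLINK text reader below is a purpose-built parser for the .ped/.map
pair (six leading .ped columns, two allele fields per SNP, phenotype
2 = affected / 1 = unaffected); it recodes every SNP so that the counted
allele is the minor allele in the full sample.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MISSING = -1


class PlinkFormatError(ValueError):
    """Malformed .ped/.map content; the message names the offending line."""


@dataclass
class GenotypeData:
    """Genotype matrix plus marker map and phenotypes."""

    values: np.ndarray          # (n, N) int8, 0/1/2 minor-allele counts, -1 missing
    snp_map: pd.DataFrame       # columns: chrom, snp_id, position
    sample_ids: list
    phenotypes: np.ndarray      # (n,) int8, 1 = affected

    def __post_init__(self) -> None:
        if self.values.shape[1] != len(self.snp_map):
            raise ValueError("snp_map length must equal the SNP count")
        for _, grp in self.snp_map.groupby("chrom", sort=False):
            if np.any(np.diff(grp["position"].to_numpy()) < 0):
                raise ValueError("positions must be non-decreasing within a chromosome")

    @property
    def positions(self) -> np.ndarray:
        return self.snp_map["position"].to_numpy()

    @property
    def chromosomes(self) -> np.ndarray:
        return self.snp_map["chrom"].to_numpy()


def read_map(map_path: str) -> pd.DataFrame:
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 4:
                raise PlinkFormatError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            rows.append(
                {"chrom": parts[0], "snp_id": parts[1], "position": int(parts[3])}
            )
    return pd.DataFrame(rows)


def read_plink_text(ped_path: str, map_path: str) -> GenotypeData:
    """Read a PLINK text .ped/.map pair into a GenotypeData.

    The minor allele of every SNP is determined from allele counts over
    the full sample and coded as the counted (B) allele; "0 0" genotypes
    become the missing sentinel.  Ties in allele frequency break toward
    the lexicographically larger allele.  Phenotypes must be 1/2.
    """
    snp_map = read_map(map_path)
    n_snps = len(snp_map)
    sample_ids = []
    phenos = []
    allele_rows = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * n_snps:
                raise PlinkFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} fields "
                    f"for {n_snps} SNPs, got {len(parts)}"
                )
            fid, iid, _, _, _, pheno = parts[:6]
            if pheno == "2":
                phenos.append(1)
            elif pheno == "1":
                phenos.append(0)
            else:
                raise PlinkFormatError(
                    f"{ped_path}:{lineno}: unknown phenotype code {pheno!r} "
                    "(expected 1 or 2)"
                )
            sample_ids.append(f"{fid}:{iid}")
            allele_rows.append(parts[6:])

    n = len(allele_rows)
    values = np.full((n, n_snps), MISSING, dtype=np.int8)
    alleles = np.array(allele_rows, dtype=object).reshape(n, n_snps, 2)
    for j in range(n_snps):
        col = alleles[:, j, :]
        observed = col[col != "0"]
        uniq, counts = np.unique(observed, return_counts=True)
        if len(uniq) > 2:
            raise PlinkFormatError(
                f"{ped_path}: SNP {snp_map['snp_id'][j]} has {len(uniq)} alleles"
            )
        if len(uniq) == 0:
            continue
        if len(uniq) == 1:
            minor = None  # monomorphic: every non-missing genotype is 0
        elif counts[0] == counts[1]:
            minor = max(uniq)  # tie: break toward the larger allele name
        else:
            minor = uniq[np.argmin(counts)]
        for i in range(n):
            a, b = col[i]
            if a == "0" or b == "0":
                if a != b:
                    raise PlinkFormatError(
                        f"{ped_path}: half-missing genotype for sample "
                        f"{sample_ids[i]} at SNP {snp_map['snp_id'][j]}"
                    )
                continue
            values[i, j] = 0 if minor is None else (a == minor) + (b == minor)
    return GenotypeData(
        values=values,
        snp_map=snp_map,
        sample_ids=sample_ids,
        phenotypes=np.asarray(phenos, dtype=np.int8),
    )


def read_genotype_tsv(geno_path: str, pheno_path: str) -> GenotypeData:
    """Read a plain TSV genotype matrix (individuals x SNPs, header of
    SNP ids) and a one-label-per-line phenotype file."""
    df = pd.read_csv(geno_path, sep="\t")
    values = df.to_numpy(dtype=np.int8)
    phenos = np.loadtxt(pheno_path, dtype=np.int8).ravel()
    snp_map = pd.DataFrame(
        {
            "chrom": "1",
            "snp_id": list(df.columns),
            "position": np.arange(1, values.shape[1] + 1),
        }
    )
    return GenotypeData(
        values=values,
        snp_map=snp_map,
        sample_ids=[f"I{i + 1}" for i in range(values.shape[0])],
        phenotypes=phenos,
    )
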