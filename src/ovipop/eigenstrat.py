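"""Plain-text EIGENSTRAT (geno/snp/ind) input and output.

Conventions match the classic EIGENSTRAT text layout: the .geno file has one
line per SNP with one character per individual giving the count of the
*reference* allele (0, 1, 2) or 9 for missing; the .snp file has columns
snp_id, chromosome, genetic position (written as 0.0), physical position,
reference allele, alternative allele; the .ind file has individual id, sex
(written as U) and population label.

Pseudohaploid individuals are expanded to the homozygous diploid scale on
output (a single observed allele written as 0 or 2); the haploid flag itself
is not representable in the format, so tables read back are diploid-coded.
Reading a trio and writing it again reproduces the files byte-for-byte.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .genotypes import MISSING, GenotypeTable, SNPPanel


def _paths(prefix):
    prefix = str(prefix)
    return prefix + ".geno", prefix + ".snp", prefix + ".ind"


def write_eigenstrat(prefix, table: GenotypeTable) -> None:
    geno_path, snp_path, ind_path = _paths(prefix)
    dos = table.diploid_scale()  # alt-allele dosage, 0/2 for pseudohaploid
    ref_count = np.where(dos == MISSING, 9, 2 - dos).astype(np.uint8)
    with open(geno_path, "w") as fh:
        for j in range(table.n_snps):
            fh.write("".join(str(c) for c in ref_count[:, j]) + "\n")
    with open(snp_path, "w") as fh:
        for row in table.panel.df.itertuples(index=False):
            fh.write(f"{row.snp_id}\t{row.chrom}\t0.0\t{row.pos}\t{row.ref}\t{row.alt}\n")
    with open(ind_path, "w") as fh:
        for ind_id, pop in zip(table.ids, table.populations):
            fh.write(f"{ind_id}\tU\t{pop}\n")


def read_eigenstrat(prefix) -> GenotypeTable:
    geno_path, snp_path, ind_path = _paths(prefix)
    snp = pd.read_csv(
        snp_path, sep="\t", header=None,
        names=["snp_id", "chrom", "gpos", "pos", "ref", "alt"],
        dtype={"chrom": str},
    )
    panel = SNPPanel(snp.drop(columns=["gpos"]))
    ind = pd.read_csv(ind_path, sep="\t", header=None,
                      names=["id", "sex", "population"])
    with open(geno_path) as fh:
        lines = [line.rstrip("\n") for line in fh]
    if len(lines) != len(panel):
        raise ValueError(".geno line count does not match .snp")
    n_ind = len(ind)
    data = np.empty((n_ind, len(panel)), dtype=np.int8)
    for j, line in enumerate(lines):
        if len(line) != n_ind:
            raise ValueError(f".geno line {j + 1} has {len(line)} characters, "
                             f"expected {n_ind}")
        ref_count = np.frombuffer(line.encode("ascii"), dtype=np.uint8) - ord("0")
        col = 2 - ref_count.astype(np.int8)
        col[ref_count == 9] = MISSING
        data[:, j] = col
    return GenotypeTable(panel, list(ind["id"]), list(ind["population"]),
                         np.full(n_ind, 2), data)
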