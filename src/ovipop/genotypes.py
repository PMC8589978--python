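"""SNP panel handling, pseudohaploid genotype calling, dataset merging and probe design.

The central containers are :class:`SNPPanel` (a biallelic marker catalogue on
1-based reference coordinates) and :class:`GenotypeTable` (individuals x SNPs
allele dosages).  Low-coverage ancient individuals are represented as
pseudohaploid: a single sequencing read stands in for the genotype at each
site, so the dosage is stored on a haploid 0/1 scale and each individual
contributes exactly one allele observation to population frequencies.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._util import as_rng, decode, is_transversion_pair

MISSING = -1

PANEL_COLUMNS = ["snp_id", "chrom", "pos", "ref", "alt", "is_transversion", "is_functional"]


class SNPPanel:
    """Catalogue of biallelic markers.

    Parameters
    ----------
    df : DataFrame with columns snp_id, chrom, pos (1-based), ref, alt and
        optionally is_functional.  ``is_transversion`` is always recomputed
        from the allele pair so the flag can never disagree with the alleles.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy().reset_index(drop=True)
        required = {"snp_id", "chrom", "pos", "ref", "alt"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"panel is missing columns: {sorted(missing)}")
        if "is_functional" not in df.columns:
            df["is_functional"] = False
        for col in ("ref", "alt"):
            bad = ~df[col].isin(list("ACGT"))
            if bad.any():
                raise ValueError(f"{col} allele must be a single base A/C/G/T")
        if (df["ref"] == df["alt"]).any():
            raise ValueError("ref and alt alleles must differ")
        if df.duplicated(subset=["chrom", "pos"]).any():
            raise ValueError("panel positions must be unique per chromosome")
        if df["snp_id"].duplicated().any():
            raise ValueError("snp_id values must be unique")
        df["is_transversion"] = [
            is_transversion_pair(r, a) for r, a in zip(df["ref"], df["alt"])
        ]
        self.df = df[PANEL_COLUMNS]

    def __len__(self) -> int:
        return len(self.df)

    @property
    def snp_ids(self) -> np.ndarray:
        return self.df["snp_id"].to_numpy()

    def subset(self, mask) -> "SNPPanel":
        return SNPPanel(self.df.loc[np.asarray(mask)])

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SNPPanel":
        return cls(pd.read_csv(path, sep="\t", dtype={"chrom": str}))


@dataclass
class GenotypeTable:
    """Individuals x SNPs allele-dosage matrix aligned to a :class:`SNPPanel`.

    ``data[i, j]`` is the alt-allele dosage of individual i at panel site j:
    0/1/2 for diploid individuals, 0/1 for pseudohaploid ones (``ploidy`` 1),
    and -1 for missing.  Pseudohaploid dosages are expanded to the diploid
    0/2 scale only at file-output time; frequency math counts them as a
    single allele observation.
    """

    panel: SNPPanel
    ids: list[str]
    populations: list[str]
    ploidy: np.ndarray  # per-individual, 1 (pseudohaploid) or 2 (diploid)
    data: np.ndarray    # int8, shape (n_individuals, n_snps)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=np.int8)
        self.ploidy = np.asarray(self.ploidy, dtype=np.int8)
        n, m = self.data.shape
        if not (len(self.ids) == len(self.populations) == len(self.ploidy) == n):
            raise ValueError("inconsistent individual metadata lengths")
        if m != len(self.panel):
            raise ValueError("data width does not match panel size")
        if not np.isin(self.ploidy, (1, 2)).all():
            raise ValueError("ploidy must be 1 or 2")
        upper = np.where(self.ploidy[:, None] == 1, 1, 2)
        valid = (self.data == MISSING) | ((self.data >= 0) & (self.data <= upper))
        if not valid.all():
            raise ValueError("dosages out of range for the stated ploidy")

    @property
    def n_individuals(self) -> int:
        return self.data.shape[0]

    @property
    def n_snps(self) -> int:
        return self.data.shape[1]

    def diploid_scale(self) -> np.ndarray:
        """Dosages with pseudohaploid individuals expanded to 0/2 (missing stays -1)."""
        out = self.data.astype(np.int8).copy()
        pseudo = self.ploidy == 1
        rows = out[pseudo]
        rows[rows == 1] = 2
        out[pseudo] = rows
        return out

    def site_counts(self) -> np.ndarray:
        """Number of non-missing sites per individual."""
        return (self.data != MISSING).sum(axis=1)

    def subset_snps(self, mask) -> "GenotypeTable":
        mask = np.asarray(mask)
        return GenotypeTable(
            self.panel.subset(mask),
            list(self.ids),
            list(self.populations),
            self.ploidy.copy(),
            self.data[:, mask],
        )

    def individuals_in(self, populations) -> np.ndarray:
        populations = set(populations)
        return np.array([p in populations for p in self.populations])


def pseudohaploid_call(reads, ref, panel: SNPPanel, trim_applied: int = 0,
                       seed=0) -> GenotypeTable:
    """Call one pseudohaploid individual from aligned reads.

    At every panel site one covering read is chosen uniformly at random
    (seeded, so deterministic); its base must match the ref or alt allele,
    otherwise the site is missing (damage artifacts and sequencing errors at
    the site are thereby rejected rather than mis-called).  Bases within
    ``trim_applied`` positions of either read end are ignored, for read sets
    that were not physically end-trimmed upstream.
    """
    if len(panel) == 0:
        raise ValueError("empty SNP panel")
    rng = as_rng(seed)

    # index endogenous reads per chromosome, ref-oriented
    by_chrom: dict[str, list] = {}
    for read in reads:
        if not read.is_endogenous:
            continue
        by_chrom.setdefault(read.chrom, []).append(read)
    for chrom_reads in by_chrom.values():
        chrom_reads.sort(key=lambda r: r.start)

    dosages = np.full(len(panel), MISSING, dtype=np.int8)
    ref_alleles = panel.df["ref"].to_numpy()
    alt_alleles = panel.df["alt"].to_numpy()
    for j, (chrom, pos) in enumerate(zip(panel.df["chrom"], panel.df["pos"])):
        p0 = pos - 1  # panel is 1-based, reads 0-based half-open
        chrom_reads = by_chrom.get(str(chrom), [])
        covering = [
            r for r in chrom_reads
            if r.start + trim_applied <= p0 < r.start + r.length - trim_applied
        ]
        if not covering:
            continue
        read = covering[rng.integers(len(covering))]
        base = read.ref_oriented_sequence()[p0 - read.start]
        if base == ref_alleles[j]:
            dosages[j] = 0
        elif base == alt_alleles[j]:
            dosages[j] = 1
    return GenotypeTable(panel, ["sample"], ["ancient"], np.array([1]),
                         dosages[None, :])


def filter_transversions(obj):
    """Restrict a panel or genotype table to transversion sites.

    Returns ``(subset, report)`` where report counts retained/removed sites.
    """
    panel = obj.panel if isinstance(obj, GenotypeTable) else obj
    mask = panel.df["is_transversion"].to_numpy()
    report = {"n_input": len(panel), "n_transversions": int(mask.sum()),
              "n_removed": int((~mask).sum())}
    if mask.sum() == 0:
        import warnings
        warnings.warn("no transversion sites in panel", stacklevel=2)
    if isinstance(obj, GenotypeTable):
        return obj.subset_snps(mask), report
    return panel.subset(mask), report


def merge_datasets(tables: list[GenotypeTable]) -> GenotypeTable:
    """Merge genotype tables on the intersection of their SNP ids.

    Allele pairs must agree exactly between tables: no strand flipping is
    attempted, and a conflict is a hard error naming the SNP.  Individuals
    are concatenated with their population labels preserved.
    """
    if not tables:
        raise ValueError("no tables to merge")
    if len(tables) == 1:
        return tables[0]

    shared = set(tables[0].panel.snp_ids)
    for t in tables[1:]:
        shared &= set(t.panel.snp_ids)
    if not shared:
        raise ValueError("no shared SNPs between tables")
    # keep the first table's ordering for the merged panel
    order = [s for s in tables[0].panel.snp_ids if s in shared]

    allele_ref: dict[str, tuple] = {}
    for t in tables:
        sub = t.panel.df.set_index("snp_id")
        for s in order:
            pair = (sub.at[s, "ref"], sub.at[s, "alt"])
            if s in allele_ref and allele_ref[s] != pair:
                raise ValueError(
                    f"conflicting allele pair at SNP {s}: "
                    f"{allele_ref[s]} vs {pair}"
                )
            allele_ref[s] = pair

    aligned = []
    for t in tables:
        idx = {s: j for j, s in enumerate(t.panel.snp_ids)}
        cols = np.array([idx[s] for s in order])
        aligned.append(t.data[:, cols])
    panel = tables[0].panel.subset(np.isin(tables[0].panel.snp_ids, order))
    return GenotypeTable(
        panel,
        sum((list(t.ids) for t in tables), []),
        sum((list(t.populations) for t in tables), []),
        np.concatenate([t.ploidy for t in tables]),
        np.concatenate(aligned, axis=0),
    )


@dataclass
class Probe:
    snp_id: str
    kind: str          # ref_center | alt_center | left_flank | right_flank
    chrom: str
    start: int         # 0-based
    sequence: str


@dataclass
class ProbeSet:
    probes: list[Probe] = field(default_factory=list)
    failures: list[str] = field(default_factory=list)  # undesignable snp_ids

    def for_snp(self, snp_id: str) -> dict[str, Probe]:
        return {p.kind: p for p in self.probes if p.snp_id == snp_id}


PROBE_LENGTH = 60
# SNP at 0-based offset 29 of the 60-mer (base 30 of 60); flanks abut the
# centred window on each side, carrying reference sequence.
_CENTER_OFFSET = 29


def design_probes(panel: SNPPanel, ref) -> ProbeSet:
    """Design four 60-base capture probes per SNP.

    Two probes are centred on the SNP and carry the reference or alternative
    allele; two flanking probes carry reference sequence immediately left and
    right of the centred window.  SNPs closer than 89 bases to a chromosome
    end are recorded as failures and skipped.
    """
    out = ProbeSet()
    seqs = {c.name: c for c in ref.chromosomes}
    for row in panel.df.itertuples(index=False):
        chrom = seqs.get(str(row.chrom))
        if chrom is None:
            out.failures.append(row.snp_id)
            continue
        p0 = row.pos - 1
        center_start = p0 - _CENTER_OFFSET
        left_start = center_start - PROBE_LENGTH
        right_start = center_start + PROBE_LENGTH
        if left_start < 0 or right_start + PROBE_LENGTH > chrom.length:
            out.failures.append(row.snp_id)
            continue
        center = decode(chrom.seq[center_start:center_start + PROBE_LENGTH])
        if center[_CENTER_OFFSET] != row.ref:
            # reference sequence must carry the ref allele at the SNP
            center = center[:_CENTER_OFFSET] + row.ref + center[_CENTER_OFFSET + 1:]
        alt_center = center[:_CENTER_OFFSET] + row.alt + center[_CENTER_OFFSET + 1:]
        left = decode(chrom.seq[left_start:left_start + PROBE_LENGTH])
        right = decode(chrom.seq[right_start:right_start + PROBE_LENGTH])
        out.probes += [
            Probe(row.snp_id, "ref_center", str(row.chrom), center_start, center),
            Probe(row.snp_id, "alt_center", str(row.chrom), center_start, alt_center),
            Probe(row.snp_id, "left_flank", str(row.chrom), left_start, left),
            Probe(row.snp_id, "right_flank", str(row.chrom), right_start, right),
        ]
    return out


def assign_ancestral_state(panel: SNPPanel, outgroup_calls) -> pd.Series:
    """Assign per-SNP ancestral alleles from two outgroup genotype vectors.

    ``outgroup_calls`` is a pair of dosage vectors (diploid scale, -1 missing)
    over the panel, one per outgroup species.  The ancestral state is the
    allele carried homozygously by both outgroups; disagreement, heterozygosity
    or missingness leaves the site 'unassigned'.
    """
    a, b = (np.asarray(v) for v in outgroup_calls)
    if a.shape != (len(panel),) or b.shape != (len(panel),):
        raise ValueError("outgroup call vectors must match panel length")
    out = []
    for j in range(len(panel)):
        da, db = a[j], b[j]
        if da == db == 0:
            out.append("ref")
        elif da == db == 2:
            out.append("alt")
        else:
            out.append("unassigned")
    return pd.Series(out, index=panel.snp_ids, name="ancestral")


def derived_allele_summary(table: GenotypeTable, ancestral_states: pd.Series,
                           ancient_ids) -> dict:
    """Summarize derived-allele carriage among ancient individuals.

    For every locus with an assigned ancestral state, flags whether at least
    one ancient individual carries the derived (non-ancestral) allele, and
    whether all ancients with data do.  Returns the per-locus flags plus the
    fraction of assigned loci with >=1 ancient carrier.
    """
    assigned = ancestral_states[ancestral_states != "unassigned"]
    if assigned.empty:
        raise ValueError("no loci with an assigned ancestral state")
    ancient_ids = set(ancient_ids)
    rows = np.array([i in ancient_ids for i in table.ids])
    if not rows.any():
        raise ValueError("no ancient individuals found in table")
    snp_index = {s: j for j, s in enumerate(table.panel.snp_ids)}

    flags = {}
    n_carrier = 0
    all_carrier_loci = []
    for snp_id, state in assigned.items():
        j = snp_index[snp_id]
        dos = table.data[rows, j]
        dos = dos[dos != MISSING]
        # derived dosage: alt if ancestral is ref, ref otherwise
        if state == "ref":
            carries = dos > 0
        else:
            ploidy_rows = table.ploidy[rows][table.data[rows, j] != MISSING]
            carries = dos < ploidy_rows
        any_c = bool(carries.any()) if dos.size else False
        all_c = bool(carries.all()) if dos.size else False
        flags[snp_id] = {"any_ancient_derived": any_c,
                         "all_ancient_derived": all_c and dos.size > 0}
        if any_c:
            n_carrier += 1
        if all_c and dos.size:
            all_carrier_loci.append(snp_id)
    return {
        "per_locus": flags,
        "n_assigned": len(assigned),
        "n_with_carrier": n_carrier,
        "fraction_with_carrier": n_carrier / len(assigned),
        "loci_all_ancients_derived": all_carrier_loci,
    }
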