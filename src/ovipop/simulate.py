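"""Synthetic data generation for the whole pipeline.

Everything downstream — damage profiling, pseudohaploid genotyping,
f-statistics, sexing, haplogroup calling — is testable on data produced here
without any external download.  The simulator emulates the study system:

* a population tree with an outgroup (wild sheep), a domestic stem, and
  diverged western and eastern domestic lineages, with per-branch genetic
  drift of Balding-Nichols form (child frequency Beta-distributed around the
  parent's with variance ``d * f * (1 - f)``);
* modern diploid breed samples and ancient pseudohaploid samples attached to
  internal branch positions;
* ancient sequencing reads on a miniature reference genome (26 autosomes of
  decreasing length, an X chromosome, and a mitogenome long enough to carry
  the control-region fragment), with log-normal fragment lengths,
  end-correlated postmortem deamination (5' C->T, 3' G->A on the strand as
  sequenced), uniform sequencing error, and an endogenous-fraction mixture
  with random non-endogenous molecules;
* replicated 144-bp mtDNA control-region fragments with haplogroup-defining
  alleles planted and optional random or convergent transitions.

Fixing the seed reproduces every artifact byte for byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd

from ._util import (BASES, as_rng, complement, decode, distinct_ints, encode,
                    transition)
from .genotypes import MISSING, GenotypeTable, SNPPanel
from .mthap import DiagnosticTable, SequenceReplicate


# ---------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class DamageModel:
    """Postmortem deamination curve: P(offset) = delta_max * exp(-decay * offset) + background.

    The default decay concentrates the damage excess within the first ~10
    bases of each end, which is what makes 10-base end trimming an effective
    remedy against damage-induced genotype artifacts.
    """
    delta_max: float = 0.30
    decay: float = 0.50
    background: float = 0.01

    def __post_init__(self):
        for name in ("delta_max", "background"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.decay < 0:
            raise ValueError("decay must be >= 0")

    def rate(self, offset) -> np.ndarray:
        return self.delta_max * np.exp(-self.decay * np.asarray(offset)) + self.background


@dataclass(frozen=True)
class FragmentLengthLaw:
    """Log-normal fragment lengths floored at a minimum (post-filter minimum 35 bp)."""
    log_mean: float = np.log(70.0)
    log_sd: float = 0.35
    min_length: int = 35

    def __post_init__(self):
        if self.min_length < 1:
            raise ValueError("min_length must be >= 1")
        if self.log_sd < 0:
            raise ValueError("log_sd must be >= 0")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        raw = np.round(rng.lognormal(self.log_mean, self.log_sd, n)).astype(np.int64)
        return np.maximum(raw, self.min_length)


@dataclass(frozen=True)
class SimulationConfig:
    n_snps: int = 20_000
    root_freq_law: tuple = (0.05, 0.95)   # Uniform(lo, hi) at the tree root
    individuals_per_pop: int = 20
    seed: int = 0
    damage: DamageModel = field(default_factory=DamageModel)
    fragment_length_law: FragmentLengthLaw = field(default_factory=FragmentLengthLaw)
    endogenous_fraction: float = 0.02
    mean_depth: float = 0.3
    seq_error: float = 0.001

    def __post_init__(self):
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        lo, hi = self.root_freq_law
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("root_freq_law bounds must satisfy 0 <= lo <= hi <= 1")
        if not 0.0 < self.endogenous_fraction <= 1.0:
            raise ValueError("endogenous_fraction must be in (0, 1]")
        if not 0.0 <= self.seq_error <= 1.0:
            raise ValueError("seq_error must be in [0, 1]")
        if self.individuals_per_pop < 1:
            raise ValueError("individuals_per_pop must be >= 1")


# ---------------------------------------------------------------------------
# population tree

LEAF_ROLES = ("outgroup", "modern_west", "modern_east")


@dataclass(frozen=True)
class TreeNode:
    name: str
    parent: str | None      # None for the root
    drift: float = 0.0      # drift coefficient of the branch above, in [0, 1)
    role: str = "internal"  # internal | outgroup | modern_west | modern_east


@dataclass(frozen=True)
class AttachmentPoint:
    """A named position part-way along an existing branch where an ancient
    sample's source population sits."""
    name: str
    branch_child: str       # the branch is parent(branch_child) -> branch_child
    fraction: float = 0.5   # how far down the branch, in (0, 1]


class PopulationTree:
    """Rooted population tree with per-branch drift and ancient attachment points."""

    def __init__(self, nodes, attachments=()):
        self.nodes = {n.name: n for n in nodes}
        if len(self.nodes) != len(list(nodes)):
            raise ValueError("duplicate node names")
        roots = [n for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise ValueError("tree must have exactly one root")
        self.root = roots[0].name
        for n in self.nodes.values():
            if n.parent is not None and n.parent not in self.nodes:
                raise ValueError(f"unknown parent {n.parent!r} of node {n.name!r}")
            if not 0.0 <= n.drift < 1.0:
                raise ValueError(f"branch drift of {n.name!r} must be in [0, 1)")
        self.children: dict[str, list[str]] = {name: [] for name in self.nodes}
        for n in self.nodes.values():
            if n.parent is not None:
                self.children[n.parent].append(n.name)
        if not any(self.nodes[l].role == "outgroup" for l in self.leaves):
            raise ValueError("tree needs at least one outgroup leaf")
        self.attachments = {}
        for a in attachments:
            if a.branch_child not in self.nodes or \
                    self.nodes[a.branch_child].parent is None:
                raise ValueError(
                    f"attachment {a.name!r} does not lie on an existing branch")
            if not 0.0 < a.fraction <= 1.0:
                raise ValueError("attachment fraction must be in (0, 1]")
            if a.name in self.nodes or a.name in self.attachments:
                raise ValueError(f"duplicate name {a.name!r}")
            self.attachments[a.name] = a

    @property
    def leaves(self) -> list[str]:
        return [name for name, ch in self.children.items() if not ch]

    def preorder(self) -> list[str]:
        order, stack = [], [self.root]
        while stack:
            name = stack.pop()
            order.append(name)
            stack.extend(sorted(self.children[name], reverse=True))
        return order

    def populations(self) -> list[str]:
        """Leaf populations plus attachment points, in stable order."""
        return [n for n in self.preorder() if not self.children[n]] + \
            sorted(self.attachments)


# Drift coefficients chosen once on realism grounds: the wild outgroup is
# strongly diverged from all domestics, the domestic stem is short, and the
# western and eastern domestic lineages are moderately differentiated, like
# present-day breed clusters.
CANONICAL_DRIFT = {"outgroup": 0.35, "stem": 0.05, "west": 0.15, "east": 0.15}


def canonical_tree(n_west: int = 1, n_east: int = 1,
                   drift: dict | None = None) -> PopulationTree:
    """Outgroup + east/west domestic split, with ancient attachment points at
    the midpoint of the western and eastern branches.

    With ``n_west``/``n_east`` > 1, each side becomes an internal node with
    that many terminal breed populations (small terminal drift 0.03 each).
    """
    d = dict(CANONICAL_DRIFT)
    if drift:
        d.update(drift)
    nodes = [
        TreeNode("root", None),
        TreeNode("outgroup", "root", d["outgroup"], "outgroup"),
        TreeNode("domestic", "root", d["stem"]),
    ]
    for side, n_pops in (("west", n_west), ("east", n_east)):
        role = f"modern_{side}"
        if n_pops == 1:
            nodes.append(TreeNode(side, "domestic", d[side], role))
        else:
            nodes.append(TreeNode(side, "domestic", d[side]))
            nodes += [TreeNode(f"{side}_{i + 1}", side, 0.03, role)
                      for i in range(n_pops)]
    attachments = [AttachmentPoint("ancient_west", "west", 0.5),
                   AttachmentPoint("ancient_east", "east", 0.5)]
    return PopulationTree(nodes, attachments)


def _drift_frequencies(f: np.ndarray, d: float,
                       rng: np.random.Generator) -> np.ndarray:
    """One Balding-Nichols drift step: Beta with mean f, variance d*f*(1-f).

    d = 0 returns the parent frequencies unchanged; frequencies already fixed
    at 0 or 1 are absorbed.
    """
    if not 0.0 <= d < 1.0:
        raise ValueError("drift coefficient must be in [0, 1)")
    if d == 0.0:
        return f.copy()
    out = f.copy()
    seg = (f > 0.0) & (f < 1.0)
    scale = (1.0 - d) / d
    out[seg] = rng.beta(f[seg] * scale, (1.0 - f[seg]) * scale)
    return out


def simulate_frequencies(tree: PopulationTree, config: SimulationConfig,
                         rng=None) -> pd.DataFrame:
    """Per-population alternative-allele frequencies under the drift tree.

    Returns a DataFrame with one row per SNP and one column per leaf
    population and attachment point.
    """
    rng = as_rng(rng if rng is not None else config.seed)
    lo, hi = config.root_freq_law
    freqs = {tree.root: rng.uniform(lo, hi, config.n_snps)}
    # attachment points subdivide their branch: the branch child is drawn
    # *through* them, so an ancient population shares the drift accumulated
    # on the branch segment above its attachment with the leaf below it
    on_branch: dict[str, list[AttachmentPoint]] = {}
    for a in tree.attachments.values():
        on_branch.setdefault(a.branch_child, []).append(a)
    for name in tree.preorder():
        node = tree.nodes[name]
        if node.parent is None:
            continue
        current = freqs[node.parent]
        done = 0.0
        for a in sorted(on_branch.get(name, []), key=lambda a: a.fraction):
            current = _drift_frequencies(current, node.drift * (a.fraction - done),
                                         rng)
            freqs[a.name] = current
            done = a.fraction
        freqs[name] = _drift_frequencies(current, node.drift * (1.0 - done), rng)
    cols = tree.populations()
    index = pd.Index([f"snp{j:06d}" for j in range(config.n_snps)], name="snp_id")
    return pd.DataFrame({c: freqs[c] for c in cols}, index=index)


# ---------------------------------------------------------------------------
# miniature reference genome

class Chromosome(NamedTuple):
    name: str
    length: int
    seq: np.ndarray | None  # uint8 base codes, or None for layout-only


@dataclass
class MiniReference:
    """Desk-scale reference: 26 autosomes, X, and MT.

    Chromosome-count geometry matches the real genome so that sexing behaves
    the same way; lengths are scaled down.
    """
    chromosomes: list[Chromosome]
    mt_reference_name: str = "MT"

    def __post_init__(self):
        names = [c.name for c in self.chromosomes]
        if not names:
            raise ValueError("reference has no chromosomes")
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        for c in self.chromosomes:
            if c.seq is not None and len(c.seq) != c.length:
                raise ValueError(f"sequence length mismatch on {c.name}")
        if self.mt_reference_name not in names:
            # minimal single-chromosome references are allowed; the MT is
            # only required where mitochondrial fragments are extracted
            self.mt_reference_name = None

    @property
    def total_length(self) -> int:
        return sum(c.length for c in self.chromosomes)

    def chromosome(self, name: str) -> Chromosome:
        for c in self.chromosomes:
            if c.name == name:
                return c
        raise KeyError(name)

    def lengths(self) -> dict[str, int]:
        return {c.name: c.length for c in self.chromosomes}


AUTOSOME_COUNT = 26
MT_LENGTH = 16_616  # long enough that control-region position 15,534 exists


def reference_layout(scale: float = 1.0) -> list[tuple[str, int]]:
    """Chromosome names and lengths of the miniature reference.

    Autosome lengths decrease linearly 3.0 Mb -> 0.5 Mb, X is 2.0 Mb, MT is
    16,616 bases (MT never scales: the control-region fragment must exist).
    """
    autosomes = np.round(np.linspace(3.0e6, 0.5e6, AUTOSOME_COUNT) * scale)
    layout = [(str(i + 1), int(l)) for i, l in enumerate(autosomes)]
    layout.append(("X", int(round(2.0e6 * scale))))
    layout.append(("MT", MT_LENGTH))
    return layout


def build_reference(scale: float = 1.0, seed: int = 0) -> MiniReference:
    """Random-sequence miniature reference (deterministic under seed)."""
    rng = as_rng(seed)
    chroms = [Chromosome(name, length, rng.integers(0, 4, length, dtype=np.uint8))
              for name, length in reference_layout(scale)]
    return MiniReference(chroms)


def copy_number(chrom_name: str, sex: str) -> int:
    if sex not in ("XX", "XY"):
        raise ValueError("sex must be 'XX' or 'XY'")
    if chrom_name == "X":
        return 1 if sex == "XY" else 2
    return 2  # autosomes and MT


# ---------------------------------------------------------------------------
# SNP panel on the miniature reference

def build_panel(config: SimulationConfig, layout=None, rng=None,
                transversion_fraction: float = 0.3,
                functional_fraction: float = 0.0) -> SNPPanel:
    """Random biallelic panel over the miniature autosomes.

    Sites are spread across autosomes proportionally to length (uniform
    positions, unique per chromosome).  A configurable fraction of allele
    pairs are transversions, the rest transitions, mirroring array content.
    """
    layout = layout if layout is not None else reference_layout()
    autosomes = [(n, l) for n, l in layout if n not in ("X", "MT")]
    rng = as_rng(rng if rng is not None else config.seed + 1)
    lengths = np.array([l for _, l in autosomes], dtype=float)
    counts = np.floor(config.n_snps * lengths / lengths.sum()).astype(int)
    for i in range(config.n_snps - counts.sum()):
        counts[i % len(counts)] += 1

    rows = []
    j = 0
    for (name, length), k in zip(autosomes, counts):
        if k == 0:
            continue
        positions = distinct_ints(rng, k, length - 200) + 100  # keep off the ends
        ref_codes = rng.integers(0, 4, k)
        is_tv = rng.random(k) < transversion_fraction
        for pos, rc, tv in zip(positions, ref_codes, is_tv):
            ref = BASES[rc]
            if tv:
                partners = [b for b in BASES
                            if (b in "AG") != (ref in "AG")]
                alt = partners[rng.integers(len(partners))]
            else:
                alt = BASES[transition(rc)]
            rows.append({"snp_id": f"snp{j:06d}", "chrom": name,
                         "pos": int(pos) + 1, "ref": ref, "alt": alt,
                         "is_functional": False})
            j += 1
    df = pd.DataFrame(rows)
    if functional_fraction > 0:
        n_func = int(round(functional_fraction * len(df)))
        idx = rng.choice(len(df), n_func, replace=False)
        df.loc[idx, "is_functional"] = True
    return SNPPanel(df)


# ---------------------------------------------------------------------------
# genotypes

def draw_genotypes(freqs: pd.DataFrame, panel: SNPPanel, mode: str,
                   config: SimulationConfig, rng=None, populations=None,
                   n_per_pop=None, missing_rate: float = 0.0) -> GenotypeTable:
    """Draw a genotype table from per-population allele frequencies.

    Diploid dosages are Binomial(2, f); pseudohaploid dosages are a single
    Bernoulli(f) draw stored on the haploid scale.  Missingness is injected
    uniformly at ``missing_rate``.
    """
    if mode not in ("diploid", "pseudohaploid"):
        raise ValueError(f"unknown mode {mode!r}")
    if not 0.0 <= missing_rate <= 1.0:
        raise ValueError("missing_rate must be in [0, 1]")
    fvals = freqs.to_numpy()
    if ((fvals < 0) | (fvals > 1)).any():
        raise ValueError("frequencies must be in [0, 1]")
    rng = as_rng(rng if rng is not None else config.seed + 2)
    populations = list(populations) if populations is not None else list(freqs.columns)
    unknown = [p for p in populations if p not in freqs.columns]
    if unknown:
        raise ValueError(f"unknown populations {unknown}")
    if n_per_pop is None:
        n_per_pop = config.individuals_per_pop if mode == "diploid" else 1

    ids, pops, blocks = [], [], []
    for pop in populations:
        f = freqs[pop].to_numpy()
        n_trials = 2 if mode == "diploid" else 1
        dosage = rng.binomial(n_trials, f, size=(n_per_pop, len(f))).astype(np.int8)
        if missing_rate > 0:
            dosage[rng.random(dosage.shape) < missing_rate] = MISSING
        blocks.append(dosage)
        ids += [f"{pop}_{i + 1}" for i in range(n_per_pop)]
        pops += [pop] * n_per_pop
    ploidy = np.full(len(ids), 2 if mode == "diploid" else 1)
    return GenotypeTable(panel, ids, pops, ploidy, np.concatenate(blocks, axis=0))


# ---------------------------------------------------------------------------
# ancient reads

class ReadRecord(NamedTuple):
    """An aligned (or non-endogenous) read; ``sequence`` is as sequenced, i.e.
    minus-strand reads store the reverse complement of the reference-oriented
    bases."""
    chrom: str
    start: int          # 0-based inclusive; half-open interval start..start+length
    length: int
    strand: str         # '+' or '-'
    sequence: str
    is_endogenous: bool

    def ref_oriented_sequence(self) -> str:
        """The read's bases laid along the reference (A at position start, ...)."""
        if self.strand == "+":
            return self.sequence
        return decode(complement(encode(self.sequence))[::-1])


def _concat_aranges(lengths: np.ndarray) -> np.ndarray:
    offsets = np.repeat(np.cumsum(lengths) - lengths, lengths)
    return np.arange(int(lengths.sum()), dtype=np.int64) - offsets


def simulate_read_counts(layout, sex: str, n_reads: int, rng=None) -> pd.DataFrame:
    """Multinomial per-chromosome read counts with intensity ~ length x copy number.

    The count vector is the sufficient statistic for coverage-based sexing;
    full read synthesis is not needed for that purpose.
    """
    rng = as_rng(rng)
    if n_reads <= 0:
        raise ValueError("n_reads must be positive")
    names = [n for n, _ in layout]
    lengths = np.array([l for _, l in layout], dtype=float)
    copies = np.array([copy_number(n, sex) for n in names], dtype=float)
    w = lengths * copies
    counts = rng.multinomial(n_reads, w / w.sum())
    return pd.DataFrame({"chrom": names, "length": lengths.astype(int),
                         "count": counts})


def simulate_ancient_reads(ref: MiniReference, config: SimulationConfig,
                           sex: str = "XX", rng=None) -> list[ReadRecord]:
    """Damaged ancient reads plus non-endogenous background molecules.

    Endogenous reads are placed uniformly with per-chromosome intensity
    proportional to length x copy number; fragment lengths follow the
    configured log-normal law; 5' C->T and 3' G->A substitutions are applied
    in read orientation with probability delta_max*exp(-decay*offset) +
    background; every base then suffers uniform sequencing error at
    ``seq_error``.  Non-endogenous reads (random sequence, unplaced) are
    appended so the endogenous share equals ``endogenous_fraction``.
    """
    if config.mean_depth <= 0:
        raise ValueError("mean_depth must be positive")
    rng = as_rng(rng if rng is not None else config.seed + 3)
    if not ref.chromosomes:
        raise ValueError("empty reference")

    target_bases = config.mean_depth * ref.total_length
    law = config.fragment_length_law
    lengths = law.draw(rng, max(16, int(target_bases / np.exp(law.log_mean)) + 16))
    while lengths.sum() < target_bases:
        lengths = np.concatenate([lengths, law.draw(rng, lengths.size)])
    n = int(np.searchsorted(np.cumsum(lengths), target_bases) + 1)
    lengths = lengths[:n]

    chrom_lengths = np.array([c.length for c in ref.chromosomes], dtype=float)
    copies = np.array([copy_number(c.name, sex) for c in ref.chromosomes],
                      dtype=float)
    w = chrom_lengths * copies
    chrom_idx = rng.choice(len(ref.chromosomes), size=n, p=w / w.sum())
    lengths = np.minimum(lengths, chrom_lengths[chrom_idx].astype(np.int64))
    starts = np.floor(
        rng.random(n) * (chrom_lengths[chrom_idx] - lengths + 1)).astype(np.int64)
    minus = rng.random(n) < 0.5

    dmg = config.damage
    reads: list[ReadRecord] = [None] * n  # type: ignore[list-item]
    for ci, chrom in enumerate(ref.chromosomes):
        sel = np.flatnonzero(chrom_idx == ci)
        if sel.size == 0:
            continue
        st, ln, mi = starts[sel], lengths[sel], minus[sel]
        within = _concat_aranges(ln)                       # position in read
        st_r = np.repeat(st, ln)
        ln_r = np.repeat(ln, ln)
        mi_r = np.repeat(mi, ln)
        refpos = np.where(mi_r, st_r + ln_r - 1 - within, st_r + within)
        base = chrom.seq[refpos].astype(np.int16)
        base[mi_r] = 3 - base[mi_r]                        # complement on minus

        off3 = ln_r - 1 - within
        u = rng.random(base.size)
        ct = (base == 1) & (u < dmg.rate(within))          # 5' C->T
        ga = (base == 2) & (u < dmg.rate(off3))            # 3' G->A
        base[ct] = 3
        base[ga] = 0
        if config.seq_error > 0:
            err = rng.random(base.size) < config.seq_error
            base[err] = (base[err] + rng.integers(1, 4, int(err.sum()))) % 4

        bounds = np.cumsum(ln)[:-1]
        for k, seq_codes in zip(sel, np.split(base.astype(np.uint8), bounds)):
            reads[k] = ReadRecord(chrom.name, int(starts[k]), int(lengths[k]),
                                  "-" if minus[k] else "+", decode(seq_codes),
                                  True)

    n_contaminant = int(round(n * (1.0 - config.endogenous_fraction)
                              / config.endogenous_fraction))
    cont_lengths = law.draw(rng, n_contaminant) if n_contaminant else np.array([], int)
    for ln in cont_lengths:
        seq = decode(rng.integers(0, 4, int(ln), dtype=np.uint8))
        reads.append(ReadRecord("*", 0, int(ln), "+", seq, False))
    return reads


def personalize_reference(ref: MiniReference, panel: SNPPanel,
                          haplotype) -> MiniReference:
    """Copy of the reference carrying an individual's alleles at panel sites.

    ``haplotype`` is a haploid dosage vector over the panel (0 = ref allele,
    1 = alt allele, missing values leave the reference base).  Reads
    simulated from the personalized reference then carry that individual's
    alleles, which is how read-level pipelines (genotyping, authentication)
    are exercised end to end.
    """
    haplotype = np.asarray(haplotype)
    if haplotype.shape != (len(panel),):
        raise ValueError("haplotype length must match panel size")
    seqs = {c.name: c.seq.copy() for c in ref.chromosomes}
    for h, row in zip(haplotype, panel.df.itertuples(index=False)):
        if h not in (0, 1):
            continue
        base = row.alt if h == 1 else row.ref
        seqs[str(row.chrom)][row.pos - 1] = encode(base)[0]
    return MiniReference([Chromosome(c.name, c.length, seqs[c.name])
                          for c in ref.chromosomes], ref.mt_reference_name)


# ---------------------------------------------------------------------------
# mtDNA replicates

def simulate_mt_replicates(diagnostic: DiagnosticTable, truth_labels: dict,
                           n_replicates: int = 2, error_rate: float = 0.0,
                           homoplasy_rate: float = 0.0, seed=0) -> list[SequenceReplicate]:
    """Replicated 144-bp fragments with the truth haplogroup's alleles planted.

    Non-diagnostic positions suffer random transitions at ``error_rate``;
    diagnostic positions suffer convergent transitions at ``homoplasy_rate``
    (applied to the planted base), emulating the homoplasy that can misassign
    fragments.
    """
    rng = as_rng(seed)
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    ref_codes = encode(diagnostic.reference_fragment)
    offsets = diagnostic.offsets
    diag_mask = np.zeros(diagnostic.fragment_length, dtype=bool)
    diag_mask[offsets] = True

    out = []
    for sample_id in sorted(truth_labels):
        label = truth_labels[sample_id]
        pattern = diagnostic.pattern(label)  # raises on unknown label
        planted = ref_codes.copy()
        planted[offsets] = encode(pattern)
        for r in range(n_replicates):
            codes = planted.copy()
            if error_rate > 0:
                hit = (rng.random(codes.size) < error_rate) & ~diag_mask
                for i in np.flatnonzero(hit):
                    codes[i] = transition(codes[i])
            if homoplasy_rate > 0:
                for o in offsets:
                    if rng.random() < homoplasy_rate:
                        codes[o] = transition(codes[o])
            out.append(SequenceReplicate(sample_id, r + 1, decode(codes)))
    return out


# ---------------------------------------------------------------------------
# file output

READ_TABLE_COLUMNS = ["chrom", "start", "length", "strand", "sequence", "endogenous"]


def write_read_table(path, reads) -> None:
    """TSV read table: chrom, 0-based half-open start/length, strand, sequence,
    endogenous flag."""
    df = pd.DataFrame(reads, columns=["chrom", "start", "length", "strand",
                                      "sequence", "is_endogenous"])
    df = df.rename(columns={"is_endogenous": "endogenous"})
    df["endogenous"] = df["endogenous"].astype(int)
    df.to_csv(path, sep="\t", index=False)


def read_read_table(path) -> list[ReadRecord]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sequence": str})
    return [ReadRecord(r.chrom, int(r.start), int(r.length), r.strand,
                       r.sequence, bool(r.endogenous))
            for r in df.itertuples(index=False)]


def write_fasta(path, records) -> None:
    """Write (name, sequence) pairs as FASTA via Biopython."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord
    seqio_write([SeqRecord(Seq(s), id=str(n), description="") for n, s in records],
                str(path), "fasta")


def write_reference_fasta(path, ref: MiniReference) -> None:
    write_fasta(path, [(c.name, decode(c.seq)) for c in ref.chromosomes])


def write_manifest(path, config: SimulationConfig, extra: dict | None = None) -> None:
    """JSON manifest of the true simulation parameters, for recovery tests."""
    payload = dataclasses.asdict(config)
    if extra:
        payload.update(extra)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
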