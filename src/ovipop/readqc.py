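"""Postmortem-damage profiling, read filtering, and contamination checks.

Ancient DNA carries cytosine deamination at fragment ends, visible as excess
C->T mismatches at 5' read ends (and G->A at 3' ends in double-stranded
libraries).  This module quantifies those mismatch profiles over the first
positions of each read end, scores single molecules for the damage signature
with a two-hypothesis log-likelihood ratio (damage curve vs sequencing error
only), applies the standard length / mismatch-ratio / damage-score filters
with end trimming, and runs the three-pronged authentication of unusually
long molecules: per-length-class damage profiles, per-class genotypes, and
the correlation of per-class outgroup-f3 affinity vectors across modern
populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import pearsonr, spearmanr

from ._util import encode
from .genotypes import GenotypeTable, SNPPanel, pseudohaploid_call
from .simulate import DamageModel, MiniReference, ReadRecord

PROFILE_WINDOW = 60


@dataclass
class MismatchProfile:
    """Per-offset mismatch rates over the first ``window`` positions of each
    read end; rates are NaN where no informative reference base was seen."""
    offsets: np.ndarray
    rate_5p_CT: np.ndarray
    rate_3p_GA: np.ndarray
    n_obs_5p: np.ndarray
    n_obs_3p: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "offset": self.offsets,
            "rate_5p_CT": self.rate_5p_CT, "n_obs_5p": self.n_obs_5p,
            "rate_3p_GA": self.rate_3p_GA, "n_obs_3p": self.n_obs_3p,
        })


@dataclass
class PMDParams:
    """Damage-score model: the alternative is the deamination curve, the null
    is base error alone; reads scoring >= threshold carry the damage signature."""
    damage: DamageModel = field(default_factory=DamageModel)
    epsilon: float = 0.001
    threshold: float = 3.0

    def __post_init__(self):
        if not 0.0 < self.epsilon < 1.0:
            raise ValueError("epsilon must be in (0, 1)")
        if not np.isfinite(self.threshold):
            raise ValueError("threshold must be finite")


def _aligned_arrays(reads, ref: MiniReference):
    """Concatenate read-oriented (read base, reference base, 5' offset, read
    length) arrays over all endogenous reads."""
    seqs = {c.name: c.seq for c in ref.chromosomes}
    ref_parts, obs_parts, lens = [], [], []
    for read in reads:
        if not read.is_endogenous:
            continue
        chrom_seq = seqs[read.chrom]
        segment = chrom_seq[read.start:read.start + read.length]
        if read.strand == "-":
            segment = (3 - segment)[::-1]
        ref_parts.append(segment.astype(np.int16))
        obs_parts.append(encode(read.sequence).astype(np.int16))
        lens.append(read.length)
    if not ref_parts:
        raise ValueError("no aligned (endogenous) reads")
    lens = np.array(lens, dtype=np.int64)
    offsets = np.concatenate([np.arange(l) for l in lens])
    return (np.concatenate(ref_parts), np.concatenate(obs_parts),
            offsets, np.repeat(lens, lens))


def damage_profile(reads, ref: MiniReference,
                   window: int = PROFILE_WINDOW) -> MismatchProfile:
    """Mismatch rates at the first ``window`` positions from each read end.

    5' rates are C->T over read-oriented reference-C sites; 3' rates are
    G->A over reference-G sites, with reverse-strand reads handled in read
    orientation (i.e. on the strand as sequenced).
    """
    refc, obs, off5, lens = _aligned_arrays(reads, ref)
    off3 = lens - 1 - off5

    def _rates(ref_code, obs_code, off):
        informative = (refc == ref_code) & (off < window)
        n = np.bincount(off[informative], minlength=window)[:window]
        hits = np.bincount(off[informative & (obs == obs_code)],
                           minlength=window)[:window]
        with np.errstate(invalid="ignore"):
            rate = np.where(n > 0, hits / np.maximum(n, 1), np.nan)
        return rate, n

    rate5, n5 = _rates(1, 3, off5)   # C -> T at 5' offsets
    rate3, n3 = _rates(2, 0, off3)   # G -> A at 3' offsets
    return MismatchProfile(np.arange(window), rate5, rate3, n5, n3)


def pmd_score(read: ReadRecord, ref: MiniReference, params: PMDParams) -> float:
    """Log-likelihood ratio of the damage model against the error-only null.

    Sums log[P(base | damage) / P(base | error)] over read-oriented
    reference-C positions (5' deamination curve) and reference-G positions
    (mirrored 3' curve).  A read spanning no informative position scores 0.
    """
    refc, obs, off5, lens = _aligned_arrays([read], ref)
    off3 = lens - 1 - off5
    eps = params.epsilon
    score = 0.0
    for ref_code, deriv_code, off in ((1, 3, off5), (2, 0, off3)):
        at = refc == ref_code
        if not at.any():
            continue
        d = params.damage.rate(off[at])
        o = obs[at]
        p_dam = np.where(o == deriv_code, d + (1 - d) * eps,
                         np.where(o == ref_code, (1 - d) * (1 - eps), np.nan))
        p_null = np.where(o == deriv_code, eps,
                          np.where(o == ref_code, 1 - eps, np.nan))
        ok = ~np.isnan(p_dam)  # bases that are neither ref nor the deamination
        score += float(np.log(p_dam[ok] / p_null[ok]).sum())  # product -> sum
    return score


@dataclass
class FilterReport:
    n_input: int = 0
    removed_length: int = 0
    removed_mismatch: int = 0
    removed_pmd: int = 0
    removed_trim: int = 0
    n_output: int = 0


def _mismatch_ratio(read: ReadRecord, seqs) -> float:
    segment = seqs[read.chrom][read.start:read.start + read.length]
    if read.strand == "-":
        segment = (3 - segment)[::-1]
    obs = encode(read.sequence)
    usable = (obs < 4) & (segment < 4)  # N excluded from both sides
    if not usable.any():
        return 0.0
    return float((obs[usable] != segment[usable]).sum() / usable.sum())


def filter_reads(reads, ref: MiniReference | None = None, min_length: int = 35,
                 max_mismatch_ratio: float = 0.10,
                 pmd_params: PMDParams | None = None, trim: int = 0):
    """Apply the standard ancient-read filters, in order.

    1. drop reads shorter than ``min_length`` (default 35);
    2. drop aligned reads with mismatches/length > ``max_mismatch_ratio``
       (default 10%);
    3. optionally keep only reads with damage score >= the PMD threshold;
    4. trim ``trim`` bases off both ends (start shifts, length shrinks);
       reads whose trimmed length is < 1 are dropped.

    Mismatch and damage-score rules need the reference and apply only to
    endogenous reads.  Returns ``(filtered_reads, FilterReport)``.  Note that
    end trimming is deliberately not idempotent: re-running with trim > 0
    trims again.
    """
    if trim < 0:
        raise ValueError("trim must be >= 0")
    reads = list(reads)
    report = FilterReport(n_input=len(reads))

    kept = [r for r in reads if r.length >= min_length]
    report.removed_length = len(reads) - len(kept)

    if ref is not None and max_mismatch_ratio is not None:
        seqs = {c.name: c.seq for c in ref.chromosomes}
        before = len(kept)
        kept = [r for r in kept
                if not r.is_endogenous
                or _mismatch_ratio(r, seqs) <= max_mismatch_ratio]
        report.removed_mismatch = before - len(kept)

    if pmd_params is not None:
        if ref is None:
            raise ValueError("PMD filtering requires the reference")
        before = len(kept)
        kept = [r for r in kept
                if not r.is_endogenous
                or pmd_score(r, ref, pmd_params) >= pmd_params.threshold]
        report.removed_pmd = before - len(kept)

    if trim > 0:
        trimmed = []
        for r in kept:
            new_len = r.length - 2 * trim
            if new_len < 1:
                continue
            trimmed.append(ReadRecord(
                r.chrom, r.start + trim, new_len, r.strand,
                r.sequence[trim:trim + new_len], r.is_endogenous))
        report.removed_trim = len(kept) - len(trimmed)
        kept = trimmed

    report.n_output = len(kept)
    return kept, report


def endogenous_fraction(reads) -> float:
    reads = list(reads)
    if not reads:
        raise ValueError("no reads")
    return sum(r.is_endogenous for r in reads) / len(reads)


@dataclass
class CoverageSummary:
    genome_depth: float
    snp_mean_depth: float | None
    per_snp_depth: np.ndarray | None


def _per_site_read_counts(reads, panel: SNPPanel) -> np.ndarray:
    starts: dict[str, list] = {}
    ends: dict[str, list] = {}
    for r in reads:
        if not r.is_endogenous:
            continue
        starts.setdefault(r.chrom, []).append(r.start)
        ends.setdefault(r.chrom, []).append(r.start + r.length)
    sorted_starts = {c: np.sort(v) for c, v in starts.items()}
    sorted_ends = {c: np.sort(v) for c, v in ends.items()}
    counts = np.zeros(len(panel), dtype=np.int64)
    for j, (chrom, pos) in enumerate(zip(panel.df["chrom"], panel.df["pos"])):
        chrom = str(chrom)
        if chrom not in sorted_starts:
            continue
        p0 = pos - 1
        n_started = np.searchsorted(sorted_starts[chrom], p0, side="right")
        n_ended = np.searchsorted(sorted_ends[chrom], p0, side="right")
        counts[j] = n_started - n_ended
    return counts


def coverage_summary(reads, ref: MiniReference,
                     panel: SNPPanel | None = None) -> CoverageSummary:
    """Genome-wide mean depth and, given a panel, mean read count over SNPs."""
    if not ref.chromosomes or ref.total_length == 0:
        raise ValueError("empty reference")
    total_bases = sum(r.length for r in reads if r.is_endogenous)
    genome_depth = total_bases / ref.total_length
    if panel is None:
        return CoverageSummary(genome_depth, None, None)
    per_snp = _per_site_read_counts(reads, panel)
    return CoverageSummary(genome_depth, float(per_snp.mean()), per_snp)


@dataclass
class AuthenticationResult:
    """Short/long-molecule comparison; no contamination verdict is issued,
    only the statistics."""
    length_cut: int
    n_short: int
    n_long: int
    profile_short: MismatchProfile
    profile_long: MismatchProfile
    calls_short: GenotypeTable
    calls_long: GenotypeTable
    f3_short: pd.Series
    f3_long: pd.Series
    spearman_rho: float
    spearman_p: float
    pearson_r: float
    pearson_p: float


def authenticate_by_length(reads, ref: MiniReference, panel: SNPPanel,
                           modern: GenotypeTable, outgroup: str,
                           length_cut: int = 90, seed: int = 0,
                           block_size: float = 5e6) -> AuthenticationResult:
    """Compare short vs long molecules of one individual.

    Reads are split at ``length_cut`` (default 90: sites with unusually good
    preservation yield average fragment sizes above 90 bp, which is what this
    check interrogates).  Each class gets its own damage profile and
    pseudohaploid genotypes; outgroup-f3 values against every modern
    population are computed per class and their rank (and product-moment)
    correlation returned.  Contaminated long molecules from another
    population depress the correlation relative to the matched case.
    """
    from .popgen import outgroup_f3  # local import; popgen does not import readqc

    endo = [r for r in reads if r.is_endogenous]
    short = [r for r in endo if r.length < length_cut]
    long_ = [r for r in endo if r.length >= length_cut]
    if not short or not long_:
        raise ValueError("both length classes must be non-empty")

    results = {}
    for name, class_reads in (("short", short), ("long", long_)):
        calls = pseudohaploid_call(class_reads, ref, panel, seed=seed)
        if (calls.data != -1).sum() == 0:
            raise ValueError(f"degenerate {name}-read class: no genotypable sites")
        calls = GenotypeTable(calls.panel, [f"{name}_reads"], [f"{name}_reads"],
                              calls.ploidy, calls.data)
        combined = GenotypeTable(
            panel,
            list(modern.ids) + list(calls.ids),
            list(modern.populations) + list(calls.populations),
            np.concatenate([modern.ploidy, calls.ploidy]),
            np.concatenate([modern.data, calls.data], axis=0),
        )
        pops = [p for p in dict.fromkeys(modern.populations) if p != outgroup]
        f3 = pd.Series(
            {p: outgroup_f3(combined, outgroup, f"{name}_reads", p,
                            block_size=block_size, jackknife=False).value
             for p in pops})
        results[name] = (damage_profile(class_reads, ref), calls, f3)

    f3_s, f3_l = results["short"][2], results["long"][2]
    rho, rho_p = spearmanr(f3_s.to_numpy(), f3_l.to_numpy())
    r, r_p = pearsonr(f3_s.to_numpy(), f3_l.to_numpy())
    return AuthenticationResult(
        length_cut, len(short), len(long_),
        results["short"][0], results["long"][0],
        results["short"][1], results["long"][1],
        f3_s, f3_l, float(rho), float(rho_p), float(r), float(r_p))
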