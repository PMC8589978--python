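"""f-statistics, weighted block jackknife, PCA with least-squares projection,
and the group-level affinity comparisons.

The outgroup f3 statistic, mean over sites of (o - a)(o - b) for allele
frequencies o, a, b, measures shared genetic drift of populations A and B
relative to an outgroup O: larger values mean greater affinity.  The
D statistic, sum of (w - x)(y - z) over sum of (w + x - 2wx)(y + z - 2yz),
tests treeness of four populations; its sign says which pair shares excess
ancestry.  Uncertainty comes from a weighted delete-one-block jackknife over
contiguous physical blocks of the genome, which is robust to local linkage
between sites.  Pseudohaploid individuals contribute a single allele
observation to population frequencies, so low-coverage ancients never
inflate sample sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu, norm, spearmanr

from .genotypes import MISSING, GenotypeTable

DEFAULT_BLOCK_SIZE = 5e6  # physical span per jackknife block, in bases


@dataclass
class FStatResult:
    kind: str                    # "f3" or "D"
    populations: tuple
    value: float
    se: float
    z: float
    p: float
    n_snps: int
    n_blocks: int
    p_adj: float | None = None


def allele_freqs(table: GenotypeTable, populations):
    """Per-population alternative-allele frequencies and observation counts.

    Returns ``(freqs, counts)``, both shaped (n_populations, n_snps); a
    diploid individual contributes two observations per non-missing site, a
    pseudohaploid individual one.  Sites with zero observations are NaN.
    """
    populations = list(populations)
    known = set(table.populations)
    unknown = [p for p in populations if p not in known]
    if unknown:
        raise ValueError(f"unknown population label(s) {unknown}")
    freqs = np.full((len(populations), table.n_snps), np.nan)
    counts = np.zeros((len(populations), table.n_snps), dtype=np.int64)
    for i, pop in enumerate(populations):
        rows = table.individuals_in([pop])
        data = table.data[rows]             # native scale: 0..ploidy
        ploidy = table.ploidy[rows][:, None]
        observed = data != MISSING
        alt = np.where(observed, data, 0).sum(axis=0)
        obs = (observed * ploidy).sum(axis=0)
        counts[i] = obs
        with np.errstate(invalid="ignore", divide="ignore"):
            freqs[i] = np.where(obs > 0, alt / np.maximum(obs, 1), np.nan)
    return freqs, counts


def _n_blocks(chrom, pos, block_size: float) -> int:
    block = (np.asarray(pos) // int(block_size)).astype(np.int64)
    return int(pd.factorize(
        pd.MultiIndex.from_arrays([np.asarray(chrom).astype(str), block]))[0].max()) + 1


def _weighted_jackknife(theta_hat: float, theta_del: np.ndarray,
                        m: np.ndarray) -> float:
    """Weighted delete-one-block jackknife SE (Busing-style pseudovalues).

    ``theta_del[j]`` is the estimate with block j removed and ``m[j]`` the
    block's site count.  With equal block sizes this reduces exactly to the
    classic delete-one jackknife variance.
    """
    n = m.sum()
    g = len(m)
    h = n / m
    theta_j = g * theta_hat - float(((1.0 - m / n) * theta_del).sum())
    tau = h * theta_hat - (h - 1.0) * theta_del
    var = float(((tau - theta_j) ** 2 / (h - 1.0)).sum() / g)
    return np.sqrt(max(var, 0.0))


def block_jackknife(per_site_terms, chrom, pos,
                    block_size: float = DEFAULT_BLOCK_SIZE):
    """Weighted block-jackknife mean and SE of per-site terms.

    The genome is partitioned into contiguous physical blocks of
    ``block_size`` bases per chromosome; empty blocks are dropped; weights
    are block site counts.  Requires at least two non-empty blocks.
    """
    terms = np.asarray(per_site_terms, dtype=float)
    chrom = np.asarray(chrom).astype(str)
    pos = np.asarray(pos)
    if not (len(terms) == len(chrom) == len(pos)):
        raise ValueError("terms, chrom and pos must be aligned")
    block = (pos // int(block_size)).astype(np.int64)
    labels = pd.factorize(pd.MultiIndex.from_arrays([chrom, block]))[0]
    g = labels.max() + 1
    if g < 2:
        raise ValueError("need >= 2 non-empty jackknife blocks")
    m = np.bincount(labels, minlength=g).astype(float)
    block_sums = np.bincount(labels, weights=terms, minlength=g)
    total, n = terms.sum(), float(len(terms))
    theta_hat = total / n
    theta_del = (total - block_sums) / (n - m)
    se = _weighted_jackknife(theta_hat, theta_del, m)
    return theta_hat, se


def _fstat_result(kind, pops, theta, se, n_snps, n_blocks) -> FStatResult:
    if se > 0:
        z = theta / se
        p = 2.0 * norm.sf(abs(z))
    else:
        z, p = (np.inf if theta > 0 else (-np.inf if theta < 0 else 0.0)), \
            (0.0 if theta != 0 else 1.0)
    return FStatResult(kind, tuple(pops), float(theta), float(se), float(z),
                       float(p), int(n_snps), int(n_blocks))


def outgroup_f3(table: GenotypeTable, outgroup: str, a: str, b: str,
                block_size: float = DEFAULT_BLOCK_SIZE,
                jackknife: bool = True) -> FStatResult:
    """Outgroup f3(O; A, B): mean over usable sites of (o - a)(o - b).

    Reported unnormalized (no heterozygosity correction), which preserves the
    relative ordering that outgroup-f3 comparisons rest on.  Sites missing in
    any of the three populations are excluded.
    """
    freqs, _ = allele_freqs(table, [outgroup, a, b])
    o, fa, fb = freqs
    usable = ~np.isnan(o) & ~np.isnan(fa) & ~np.isnan(fb)
    if not usable.any():
        raise ValueError("no sites usable in all three populations")
    terms = (o[usable] - fa[usable]) * (o[usable] - fb[usable])
    n_snps = int(usable.sum())
    if not jackknife:
        return _fstat_result("f3", (outgroup, a, b), terms.mean(), np.nan,
                             n_snps, 0)
    chrom = table.panel.df["chrom"].astype(str).to_numpy()[usable]
    pos = table.panel.df["pos"].to_numpy()[usable]
    theta, se = block_jackknife(terms, chrom, pos, block_size)
    g = _n_blocks(chrom, pos, block_size)
    return _fstat_result("f3", (outgroup, a, b), theta, se, n_snps, g)


def d_statistic(table: GenotypeTable, w: str, x: str, y: str, z: str,
                block_size: float = DEFAULT_BLOCK_SIZE,
                jackknife: bool = True) -> FStatResult:
    """D(W, X; Y, Z) = sum (w-x)(y-z) / sum [(w+x-2wx)(y+z-2yz)] over usable sites.

    SE, Z and two-sided normal p come from a weighted block jackknife on the
    numerator/denominator ratio.  D is antisymmetric under swapping W with X
    or Y with Z, and lies in [-1, 1] when the denominator is positive.
    """
    freqs, _ = allele_freqs(table, [w, x, y, z])
    fw, fx, fy, fz = freqs
    usable = ~np.isnan(freqs).any(axis=0)
    if not usable.any():
        raise ValueError("no sites usable in all four populations")
    fw, fx, fy, fz = (f[usable] for f in (fw, fx, fy, fz))
    num = (fw - fx) * (fy - fz)
    den = (fw + fx - 2 * fw * fx) * (fy + fz - 2 * fy * fz)
    den_sum = den.sum()
    if den_sum == 0:
        raise ValueError("degenerate D statistic: zero denominator")
    theta_hat = num.sum() / den_sum
    n_snps = int(usable.sum())
    pops = (w, x, y, z)
    if not jackknife:
        return _fstat_result("D", pops, theta_hat, np.nan, n_snps, 0)

    chrom = table.panel.df["chrom"].astype(str).to_numpy()[usable]
    pos = table.panel.df["pos"].to_numpy()[usable]
    block = (pos // int(block_size)).astype(np.int64)
    labels = pd.factorize(pd.MultiIndex.from_arrays([chrom, block]))[0]
    g = labels.max() + 1
    if g < 2:
        raise ValueError("need >= 2 non-empty jackknife blocks")
    m = np.bincount(labels, minlength=g).astype(float)
    num_sums = np.bincount(labels, weights=num, minlength=g)
    den_sums = np.bincount(labels, weights=den, minlength=g)
    del_den = den_sum - den_sums
    if (del_den == 0).any():
        raise ValueError("degenerate jackknife: a delete-one denominator is zero")
    theta_del = (num.sum() - num_sums) / del_den
    se = _weighted_jackknife(theta_hat, theta_del, m)
    return _fstat_result("D", pops, theta_hat, se, n_snps, g)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D array of p-values")
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.minimum(adj, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def annotate_bh(results: list[FStatResult]) -> list[FStatResult]:
    """Fill ``p_adj`` across a batch of tests (the batch is the correction unit)."""
    adj = bh_adjust([r.p for r in results])
    for r, a in zip(results, adj):
        r.p_adj = float(a)
    return results


@dataclass
class PCAModel:
    snp_ids: np.ndarray
    means: np.ndarray            # per-SNP mean dosage (diploid scale)
    scales: np.ndarray           # per-SNP sqrt(p(1-p)), p = mean/2
    loadings: np.ndarray         # (k, n_snps), orthonormal rows
    eigenvalues: np.ndarray
    explained_variance_ratio: np.ndarray
    coordinates: pd.DataFrame    # fitted individuals x components

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]


def pca_fit(table: GenotypeTable, n_components: int | None = None) -> PCAModel:
    """smartpca-style PCA of a (modern, diploid) genotype table.

    Dosages are centred by the per-SNP mean and scaled by sqrt(p(1-p)) with
    p the mean dosage over 2; residual missingness at fit time is mean
    imputed (i.e. contributes nothing after centring).  Monomorphic sites are
    dropped; an input with fewer than 2 polymorphic sites or 2 individuals is
    an error.
    """
    if table.n_individuals < 2:
        raise ValueError("PCA needs >= 2 individuals")
    dos = table.diploid_scale().astype(float)
    dos[dos == MISSING] = np.nan
    means = np.nanmean(dos, axis=0)
    p_hat = means / 2.0
    scales = np.sqrt(p_hat * (1.0 - p_hat))
    poly = np.isfinite(scales) & (scales > 0)
    if poly.sum() < 2:
        raise ValueError("PCA needs >= 2 polymorphic SNPs")
    x = (dos[:, poly] - means[poly]) / scales[poly]
    x[np.isnan(x)] = 0.0  # mean imputation after standardization
    k_max = min(x.shape) - (1 if x.shape[0] <= x.shape[1] else 0)
    k = min(n_components or 10, max(k_max, 1))
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    eigenvalues = s ** 2 / (x.shape[0] - 1)
    evr = s ** 2 / (s ** 2).sum()
    coords = pd.DataFrame(
        (u * s)[:, :k], index=list(table.ids),
        columns=[f"PC{i + 1}" for i in range(k)])
    coords["population"] = list(table.populations)
    return PCAModel(table.panel.snp_ids[poly], means[poly], scales[poly],
                    vt[:k], eigenvalues[:k], evr[:k], coords)


def pca_project(model: PCAModel, sample_dosages, snp_ids=None) -> np.ndarray:
    """Least-squares projection of a (possibly very incomplete) sample.

    ``sample_dosages`` is a diploid-scale dosage vector (missing = -1 or
    NaN) over ``snp_ids`` (default: the model's SNPs).  The solve uses only
    the sample's non-missing SNPs known to the model, after applying the
    model's centring and scaling; no imputation is done at projection time.
    """
    x = np.asarray(sample_dosages, dtype=float)
    x[x == MISSING] = np.nan
    if snp_ids is None:
        if len(x) != len(model.snp_ids):
            raise ValueError("dosage vector does not match model SNPs")
        observed = np.isfinite(x)
        xs = x[observed]
        load = model.loadings[:, observed]
        means, scales = model.means[observed], model.scales[observed]
    else:
        pos = {s: i for i, s in enumerate(model.snp_ids)}
        idx, xs_list = [], []
        for s, v in zip(snp_ids, x):
            if s in pos and np.isfinite(v):
                idx.append(pos[s])
                xs_list.append(v)
        idx = np.array(idx, dtype=int)
        xs = np.array(xs_list)
        load = model.loadings[:, idx]
        means, scales = model.means[idx], model.scales[idx]
    if xs.size < 2:
        raise ValueError("fewer than 2 usable SNPs for projection")
    standardized = (xs - means) / scales
    coords, *_ = np.linalg.lstsq(load.T, standardized, rcond=None)
    return coords


@dataclass
class GroupComparison:
    medians: dict
    u_statistic: float
    p_value: float


def compare_affinity_groups(values, groups) -> GroupComparison:
    """Two-sided Mann-Whitney U on f3 values split by group label.

    ``values`` maps population -> f3 value; ``groups`` maps population -> one
    of exactly two group labels.
    """
    values = pd.Series(values)
    groups = pd.Series(groups)
    labels = list(pd.unique(groups[values.index]))
    if len(labels) != 2:
        raise ValueError("exactly two groups required")
    split = {lab: values[groups[values.index] == lab].to_numpy()
             for lab in labels}
    if any(len(v) == 0 for v in split.values()):
        raise ValueError("both groups must be non-empty")
    u, p = mannwhitneyu(split[labels[0]], split[labels[1]],
                        alternative="two-sided")
    return GroupComparison({lab: float(np.median(v)) for lab, v in split.items()},
                           float(u), float(p))


def correlate_f3(f3_vector_1, f3_vector_2):
    """Spearman rank correlation of two f3 vectors paired by population."""
    v1 = pd.Series(f3_vector_1)
    v2 = pd.Series(f3_vector_2)
    if len(v1) != len(v2):
        raise ValueError("f3 vectors differ in length")
    if len(v1) < 3:
        raise ValueError("need at least 3 paired populations")
    if not v1.index.equals(v2.index):
        v2 = v2.reindex(v1.index)
        if v2.isna().any():
            raise ValueError("f3 vectors are not over the same populations")
    rho, p = spearmanr(v1.to_numpy(), v2.to_numpy())
    return float(rho), float(p)
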