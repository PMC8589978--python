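# Methods

This note documents the models behind `ovipop`, the choices made where the
design was genuinely open, and what the synthetic-data generator does and
does not emulate.

## Study system and scope

The pipeline targets a recurring situation in archaeogenetics: a handful of
low-coverage ancient individuals (here, Neolithic Anatolian sheep) compared
against genotyped modern populations that fall into two diverged clusters
(European/"west" and Asian-African/"east" breeds), with a wild outgroup
(Argali-like) anchoring the comparisons. The questions the statistics answer
are (i) are the ancient molecules authentic, (ii) what sex were the
individuals, (iii) which modern cluster do the ancients share more drift
with, and (iv) what do the maternal (mtDNA) lineages say. Everything runs on
synthetic data; no external downloads are needed or used.

## Synthetic-data generator

**Allele frequencies.** Populations sit on a rooted tree; each branch
carries a drift coefficient $d \in [0, 1)$. A child's frequency is drawn
from a Beta distribution with mean equal to the parent's frequency $f$ and
variance $d\,f(1-f)$ (the Balding–Nichols parameterization), with
frequencies already fixed at 0 or 1 absorbed. The closed-form moments make
analytic oracles possible (e.g. the mean squared frequency change along a
branch is exactly $d\,f(1-f)$). Root frequencies are Uniform(0.05, 0.95),
which keeps most sites informative, as array-ascertained panels are.

**Ancient samples as attachment points.** An ancient population is a named
point part-way along an existing branch. The branch is simulated *through*
the attachment (parent → attachment → child as chained drift steps with
coefficients $d\,t$ and $d\,(1-t)$), so the ancient shares the drift of the
branch segment above it with the modern leaf below it — this covariance is
what f3/D/PCA detect. Exact Beta-step composition makes branch variance only
approximately additive ($d - d^2 t(1-t)$ instead of $d$), a second-order
effect at the drift values used.

**Canonical tree.** The default scenario has an outgroup branch ($d=0.35$),
a short domestic stem ($d=0.05$) and west/east branches ($d=0.15$ each),
with ancient attachment points at both branch midpoints. These values were
fixed once on realism grounds — wild outgroups are strongly diverged from
all domestics, while the two modern breed clusters are moderately
differentiated — and all structure-recovery tests run against them
unchanged.

**Genotypes.** Diploid dosages are Binomial(2, f); pseudohaploid dosages a
single Bernoulli(f) draw stored on a haploid 0/1 scale and expanded to 0/2
only for EIGENSTRAT output. Missingness is injected uniformly (default 60%
for ancients in the canonical scenario, matching a few-thousand-usable-SNP
regime).

**Miniature reference.** 26 autosomes with lengths decreasing linearly from
3.0 Mb to 0.5 Mb, X = 2.0 Mb, MT = 16,616 bases (so the control-region
fragment interval exists at full scale), random sequence under a fixed seed.
Chromosome-count geometry matches the real karyotype because the sexing
regression consumes exactly that geometry; absolute lengths are scaled to
desk size, and a `scale` parameter shrinks everything but the MT further for
fast tests.

**Reads.** Endogenous reads are placed uniformly with per-chromosome
intensity proportional to length × copy number (X copy 1 in XY, 2 in XX).
Fragment lengths are log-normal (median ≈ 70 bp, log-sd 0.35) floored at
35 bp, the post-filter minimum. Postmortem deamination is applied on the
strand as sequenced: C→T with probability
$\delta_{\max} e^{-\lambda\,\text{offset}} + b$ from the 5' end and G→A
mirrored from the 3' end (double-stranded library convention), then a
uniform sequencing-error rate. Defaults $\delta_{\max}=0.30$, $\lambda=0.5$
per base, $b=0.01$: the terminal rate sits in the empirically observed
20–40% range, and the decay concentrates the excess within the first ~10
bases, which is precisely the regime in which 10-base end trimming removes
damage-induced genotype artifacts. Non-endogenous molecules (random
sequence, unplaced) are mixed in so the endogenous share matches the
configured fraction (default 2%, the median observed for usable ancient
libraries). For coverage-based sexing the per-chromosome *count* vector is
the sufficient statistic, so a counts-level simulator (multinomial over
chromosomes) is provided alongside full read synthesis and is what the
replicated sexing experiments use.

**mtDNA replicates.** The 144-base control-region fragment (reference
positions 15,391–15,534, 1-based inclusive) with the truth haplogroup's
diagnostic alleles planted; random transitions at non-diagnostic sites at an
error rate, and convergent transitions at diagnostic sites at a homoplasy
rate — the latter reproduces the known misassignment mode of fragment-based
haplogroup calling. The diagnostic table itself is synthetic (the real one
lives in supplementary material not shipped here) but preserves the
geometry: five sites inside the fragment, transition-derived alleles,
pairwise-distinct patterns, reference sequence belonging to haplogroup B.

**What the generator does not emulate.** Indels, base-quality strings,
reference bias, linkage disequilibrium (sites are exchangeable — consistent
with the f-statistics used, but it means LD-aware methods cannot be
validated here), selection, and sequencing-error structure beyond a uniform
substitution rate. Passing tests therefore demonstrate correctness of the
statistical machinery under the stated models, not robustness to every
artifact of real ancient-DNA data.

## Read QC and authentication

Damage profiles count C→T mismatches over read-oriented reference-C sites at
5' offsets 0–59 and G→A over reference-G sites at 3' offsets, with
reverse-strand reads handled in read orientation; rates are flagged
undefined where no informative site was observed. The PMD score is a
simplified two-hypothesis log-likelihood ratio — damage-curve model against
sequencing-error-only null — summed over informative positions; it preserves
the decision semantics of the standard score threshold 3 without modelling
base qualities (which are not simulated). Filtering applies, in order:
minimum length 35, mismatch ratio > 10% removal (N excluded from numerator
and denominator), optional PMD-score threshold, then end trimming (10 bases
in the study's pipeline); trimming is deliberately not idempotent.

The long-molecule authentication splits an individual's reads at 90 bases
(the observed average at the best-preserved site exceeded 90 bp), profiles
damage per class, genotypes each class separately, and correlates the two
classes' outgroup-f3 vectors across modern populations. Both Spearman and
Pearson coefficients are reported because the source analysis names both;
neither is privileged. No contamination verdict is issued — the statistics
are returned for the analyst to judge.

## f-statistics and uncertainty

f3 is reported unnormalized (plain mean of $(o-a)(o-b)$), with no
heterozygosity correction for pseudohaploid outgroups: only the relative
ordering of f3 values enters the downstream comparisons. The D denominator
is the standard $(w+x-2wx)(y+z-2yz)$ form. Uncertainty uses a weighted
delete-one-block jackknife (Busing-style pseudovalues, weights = block SNP
counts) over contiguous physical blocks, default 5 Mb of the miniature
genome — the genuine tuning knob here, chosen so the canonical genome yields
~26 blocks; with equal block sizes the formula reduces exactly to the
classic delete-one jackknife, which is how it is tested. Two-sided p-values
come from the normal approximation of the jackknife Z, and batches of tests
are Benjamini–Hochberg adjusted with monotonicity enforcement.

PCA standardizes dosages by $\sqrt{\hat p(1-\hat p)}$ with $\hat p$ the mean
dosage over 2 (smartpca's scaling), drops monomorphic sites, mean-imputes
residual missingness at fit time only, and projects incomplete samples by
least squares restricted to their observed SNPs — projection never imputes.
Group-level affinity comparisons use the two-sided Mann–Whitney U on f3
values and Spearman correlations between f3 vectors.

## Molecular sexing

Mapped-read counts per chromosome are normalized by chromosome length; the
X is excluded and a loess curve (tricube weights, span 0.80, local degree 2,
degrading to degree 1 below 10 autosomes) is fit to autosomal intensity
against length, then evaluated at the X's length. The 95% interval is a
*t-based prediction interval*: residual variance plus curve variance, with
residual degrees of freedom = autosome count − trace of the smoother matrix,
floored at 2. A prediction interval (rather than a mean-curve confidence
interval) is the only construction under which a true XX library's observed
X intensity falls inside the interval ~95% of the time, which is the
operational meaning of testing the XX null; it is mildly conservative for
the X because long chromosomes carry below-average sampling noise. The
decision rule: XX if the observed intensity is inside the interval;
XY if the observed/expected ratio lies in [0.35, 0.65] *and* the intensity
is outside the interval; ambiguous otherwise. The XY band is this package's
own choice — the source analysis tests only the XX null and never states an
XY acceptance region — chosen symmetric around the 0.5 single-copy
expectation and conservative, with boundary cases returning ambiguous
rather than a forced call. The XX expectation is predicted at the X's
physical length (not half of it); the ratio scale makes the convention
immaterial to the calls.

## mtDNA haplogroups

A replicate is classified by its five diagnostic bases: exact pattern match
wins; otherwise the nearest pattern by Hamming distance is taken when unique
and at distance 1 (a single convergent transition can be rescued, with the
site recorded as a conflict); ties, larger distances, or N at a diagnostic
site (a mismatch to every pattern) give "unassigned". Consensus per sample:
two or more concordant replicates → that label at high confidence; two
discordant → a third round decides by majority (no majority → unassigned);
a single replicate → its label at low confidence; a mitogenome-based call,
where available, overrides the fragment consensus. Frequency confidence
intervals are exact Clopper–Pearson (the construction that reproduces the
printed worked example: 4 carriers of 79 → [1%, 12%] after rounding, where
Wilson would print a 2% lower bound). Composition differences between groups
use an exact conditional test on the haplogroup × group table — full
enumeration over tables with fixed margins, reducing to Fisher's exact test
in the 2×2 case — with effect size $w = \sqrt{\chi^2 / N}$.

## Numerical and engineering choices

- Coordinates: panels are 1-based; read tables 0-based half-open; the
  conversion happens in exactly one place per consumer.
- EIGENSTRAT text I/O is byte-exact round-tripping; pseudohaploid
  individuals are written as homozygous diploid (the format cannot carry
  the haploid flag).
- Merging datasets intersects SNP ids and treats allele-pair conflicts as
  fatal; no strand flipping is attempted (panels are treated as
  strand-consistent, true within a single array ecosystem).
- Capture probes: 60-mers with the SNP at 0-based offset 29 (the off-center
  convention is unstated upstream and fixed here), flanks abutting the
  centered window; SNPs within 89 bases of a chromosome end are recorded as
  per-SNP failures without aborting the batch.
- Problem sizes in the test suite (20,000 SNPs, 20 individuals per
  population, 100 seeded replicates for stochastic recoveries, 1%-scale
  reference for read-level work) were chosen as the smallest sizes at which
  the expected effects dominate Monte-Carlo noise by a comfortable margin.
- All simulation entry points are deterministic under a seed; identical
  seeds reproduce outputs byte for byte.

## Known limitations

- The exact block length and denominator variant used by the reference
  implementations of f-statistics are not published; the defaults here are
  declared, not inferred, and equal-block correctness is what is guaranteed.
- The PMD score omits base qualities and the full damage-model likelihood;
  scores are comparable within this package, not numerically interchangeable
  with PMDtools output.
- Sexing assumes a karyotypically normal individual and an X assembled at
  roughly correct length; no Y-based confirmation is possible (no Y in the
  reference layout, mirroring the assembly the study used).
- The r×2 exact test enumerates tables with fixed margins; it is intended
  for the small contingency tables that haplogroup comparisons produce, not
  for large counts where the enumeration explodes.
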