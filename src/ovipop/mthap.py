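"""Mitochondrial haplogroup classification from a 144-bp control-region fragment.

Domestic sheep fall into five principal maternal lineages, haplogroups A-E.
A short control-region fragment (reference positions 15,391-15,534, 144 bases,
1-based inclusive) carries diagnostic sites whose alleles separate the five
haplogroups, which makes the fragment usable on poorly preserved material.
This module classifies single sequence replicates against a diagnostic-site
table, runs the replicate-consensus workflow (at least two concordant
sequences per sample, third-round majority on discrepancy, single sequences
flagged low-confidence, mitogenome-based calls taking precedence), validates
fragment-based accuracy against full mitogenomes, and computes haplogroup
frequency statistics with exact binomial confidence intervals and exact
contingency tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import gammaln
from statsmodels.stats.proportion import proportion_confint

from ._util import BASES, as_rng, transition, encode

HAPLOGROUPS = ("A", "B", "C", "D", "E")

FRAGMENT_START = 15391  # 1-based inclusive
FRAGMENT_END = 15534
FRAGMENT_LENGTH = FRAGMENT_END - FRAGMENT_START + 1  # 144


@dataclass
class DiagnosticTable:
    """Diagnostic control-region sites for haplogroups A-E.

    ``sites`` has columns position (1-based genome coordinate inside the
    fragment), ref_base, and one expected-base column per haplogroup.
    ``reference_fragment`` is the 144-base reference sequence of the fragment.
    """

    reference_name: str
    reference_fragment: str
    sites: pd.DataFrame
    fragment_start: int = FRAGMENT_START
    fragment_end: int = FRAGMENT_END

    def __post_init__(self):
        if len(self.reference_fragment) != self.fragment_length:
            raise ValueError("reference fragment length does not match interval")
        pos = self.sites["position"].to_numpy()
        if ((pos < self.fragment_start) | (pos > self.fragment_end)).any():
            raise ValueError("diagnostic site outside the fragment interval")
        pats = {h: tuple(self.sites[h]) for h in HAPLOGROUPS}
        for h1, h2 in itertools.combinations(HAPLOGROUPS, 2):
            if pats[h1] == pats[h2]:
                raise ValueError(f"haplogroups {h1} and {h2} share a pattern")
        for off, rb in zip(self.offsets, self.sites["ref_base"]):
            if self.reference_fragment[off] != rb:
                raise ValueError("ref_base disagrees with reference fragment")

    @property
    def fragment_length(self) -> int:
        return self.fragment_end - self.fragment_start + 1

    @property
    def n_sites(self) -> int:
        return len(self.sites)

    @property
    def offsets(self) -> np.ndarray:
        """0-based offsets of the diagnostic sites within the fragment."""
        return self.sites["position"].to_numpy() - self.fragment_start

    def pattern(self, haplogroup: str) -> str:
        if haplogroup not in HAPLOGROUPS:
            raise ValueError(f"unknown haplogroup {haplogroup!r}")
        return "".join(self.sites[haplogroup])


# Diagnostic positions of the synthetic default table (inside 15391-15534).
_DEFAULT_POSITIONS = (15415, 15438, 15462, 15495, 15520)
# Which sites each haplogroup carries in the derived (transition) state.
# B equals the reference at every site (the reference mitogenome is a
# haplogroup-B sequence); the patterns are pairwise distinct.
_DERIVED_SITES = {"A": (0, 4), "B": (), "C": (1,), "D": (2,), "E": (3,)}


def synthetic_diagnostic_table(mt_sequence: str,
                               reference_name: str = "MT") -> DiagnosticTable:
    """Build the default five-site diagnostic table on a synthetic mitogenome.

    The real diagnostic table lives in supplementary material not shipped
    here; this synthetic stand-in preserves its geometry: five sites inside
    the 144-bp fragment, transition-derived alleles, pairwise-distinct
    patterns, and a reference sequence belonging to haplogroup B.
    """
    if len(mt_sequence) < FRAGMENT_END:
        raise ValueError("mitogenome shorter than the fragment interval")
    fragment = mt_sequence[FRAGMENT_START - 1:FRAGMENT_END]
    rows = []
    for k, pos in enumerate(_DEFAULT_POSITIONS):
        ref_base = fragment[pos - FRAGMENT_START]
        derived = BASES[transition(encode(ref_base)[0])]
        row = {"position": pos, "ref_base": ref_base}
        for h in HAPLOGROUPS:
            row[h] = derived if k in _DERIVED_SITES[h] else ref_base
        rows.append(row)
    return DiagnosticTable(reference_name, fragment, pd.DataFrame(rows))


@dataclass
class SequenceReplicate:
    sample_id: str
    replicate: int
    sequence: str
    source: str = "sanger_fragment"  # or "mitogenome"

    def __post_init__(self):
        if any(b not in "ACGTN" for b in self.sequence):
            raise ValueError("sequence may contain only A/C/G/T/N")


@dataclass
class HaplogroupCall:
    sample_id: str
    label: str                      # A-E or "unassigned"
    n_replicates: int
    n_concordant: int
    confidence: str                 # "high" (>=2 concordant) or "low" (single sequence)
    conflicts: list = field(default_factory=list)
    mitogenome_override: bool = False


def extract_fragment(mitogenome_sequence: str, table: DiagnosticTable) -> str:
    """Slice the 144-base control-region fragment out of a mitogenome."""
    if len(mitogenome_sequence) < table.fragment_end:
        raise ValueError(
            f"sequence length {len(mitogenome_sequence)} does not cover "
            f"position {table.fragment_end}"
        )
    return mitogenome_sequence[table.fragment_start - 1:table.fragment_end]


def call_haplogroup(replicate, table: DiagnosticTable):
    """Classify one fragment sequence by its diagnostic-site alleles.

    Exact match to one haplogroup's pattern wins; otherwise the nearest
    pattern by Hamming distance over the diagnostic sites is taken when it is
    unique and at distance 1 (a single convergent transition can be rescued);
    ties or distance > 1 give "unassigned".  N at a diagnostic site counts as
    a mismatch to every pattern.

    Returns ``(label, conflicts)`` where conflicts lists the diagnostic
    positions whose base deviates from the called pattern (or from all
    patterns when unassigned).
    """
    seq = replicate.sequence if isinstance(replicate, SequenceReplicate) else replicate
    if len(seq) != table.fragment_length:
        raise ValueError(
            f"sequence length {len(seq)} != fragment length {table.fragment_length}"
        )
    observed = "".join(seq[o] for o in table.offsets)
    positions = table.sites["position"].to_numpy()

    distances = {}
    for h in HAPLOGROUPS:
        pat = table.pattern(h)
        distances[h] = sum(1 for a, b in zip(observed, pat)
                           if a != b or a == "N")
    best = min(distances.values())
    winners = [h for h, d in distances.items() if d == best]
    if best <= 1 and len(winners) == 1:
        label = winners[0]
        pat = table.pattern(label)
        conflicts = [int(positions[i]) for i, (a, b) in
                     enumerate(zip(observed, pat)) if a != b or a == "N"]
        return label, conflicts
    return "unassigned", [int(p) for p in positions]


def consensus_call(sample_id: str, replicates, table: DiagnosticTable,
                   mitogenome_call: str | None = None) -> HaplogroupCall:
    """Consensus haplogroup for one sample's replicate sequences.

    Two or more concordant replicate labels give that label at high
    confidence; two discordant replicates require a third and take the
    majority (no majority -> unassigned); a single replicate gives its label
    at low confidence.  A mitogenome-based call, when provided, overrides the
    fragment consensus.
    """
    replicates = list(replicates)
    if not replicates:
        raise ValueError("no replicates for sample")
    labels = []
    conflicts: list = []
    for rep in replicates:
        lab, confl = call_haplogroup(rep, table)
        labels.append(lab)
        conflicts.extend(confl)
    counts = pd.Series(labels).value_counts()
    top = int(counts.iloc[0])
    if len(replicates) == 1:
        label, n_conc, confidence = labels[0], 1, "low"
    elif top >= 2 and (counts == top).sum() == 1:
        label, n_conc, confidence = counts.index[0], top, "high"
    else:
        # discordant without a majority (e.g. two replicates disagreeing and
        # no third round available)
        label, n_conc, confidence = "unassigned", top, "high"
    call = HaplogroupCall(sample_id, label, len(replicates), n_conc,
                          confidence, sorted(set(conflicts)))
    if mitogenome_call is not None:
        if mitogenome_call != call.label:
            call.label = mitogenome_call
            call.mitogenome_override = True
            call.confidence = "high"
        else:
            call.mitogenome_override = False
    return call


def validate_fragment_accuracy(mitogenomes, table: DiagnosticTable):
    """Accuracy of fragment-based haplogroup assignment on labelled mitogenomes.

    ``mitogenomes`` is an iterable of ``(sequence, truth_label)`` pairs.
    Returns ``(accuracy, confusion)`` where confusion is a DataFrame with
    truth labels as rows and fragment-based calls as columns.
    """
    mitogenomes = list(mitogenomes)
    if not mitogenomes:
        raise ValueError("no mitogenomes supplied")
    labels = list(HAPLOGROUPS) + ["unassigned"]
    confusion = pd.DataFrame(0, index=list(HAPLOGROUPS), columns=labels)
    n_correct = 0
    for seq, truth in mitogenomes:
        frag = extract_fragment(seq, table)
        called, _ = call_haplogroup(frag, table)
        confusion.loc[truth, called] += 1
        if called == truth:
            n_correct += 1
    return n_correct / len(mitogenomes), confusion


def haplogroup_frequencies_ci(calls, confidence_set: str = "all",
                              level: float = 0.95) -> pd.DataFrame:
    """Per-group haplogroup frequencies with exact Clopper-Pearson intervals.

    ``calls`` is a DataFrame with columns sample_id, label, confidence and
    group.  ``confidence_set`` is "all" or "high_only" (the latter drops
    single-amplification, low-confidence samples).  Unassigned samples stay
    in the denominator.
    """
    if confidence_set not in ("all", "high_only"):
        raise ValueError("confidence_set must be 'all' or 'high_only'")
    df = pd.DataFrame(calls)
    if confidence_set == "high_only":
        df = df[df["confidence"] == "high"]
    rows = []
    for group, sub in df.groupby("group"):
        n = len(sub)
        if n == 0:
            raise ValueError(f"empty group {group!r}")
        for h in HAPLOGROUPS:
            k = int((sub["label"] == h).sum())
            lo, hi = proportion_confint(k, n, alpha=1 - level, method="beta")
            rows.append({"group": group, "haplogroup": h, "count": k, "n": n,
                         "frequency": k / n, "ci_low": lo, "ci_high": hi})
    return pd.DataFrame(rows)


def binomial_ci(k: int, n: int, level: float = 0.95):
    """Exact (Clopper-Pearson) binomial confidence interval for k successes of n."""
    if not 0 <= k <= n or n <= 0:
        raise ValueError("need 0 <= k <= n, n > 0")
    return proportion_confint(k, n, alpha=1 - level, method="beta")


@dataclass
class FrequencyComparison:
    table: pd.DataFrame        # haplogroup x group contingency counts
    p_value: float
    cohens_w: float
    frequencies: pd.DataFrame  # per group per haplogroup with CIs


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def exact_rx2_test(table: np.ndarray) -> float:
    """Exact conditional test on an r x 2 contingency table.

    Enumerates all tables with the observed margins; the p-value is the total
    probability (multivariate hypergeometric, margins fixed) of tables no
    more probable than the observed one.  For 2 x 2 tables this is Fisher's
    exact test.
    """
    table = np.asarray(table, dtype=np.int64)
    if table.ndim != 2 or table.shape[1] != 2:
        raise ValueError("expected an r x 2 table")
    if table.sum() == 0:
        raise ValueError("all-zero contingency table")
    rows = table.sum(axis=1)
    c1 = int(table[:, 0].sum())

    logp_obs = sum(_log_comb(rows[i], table[i, 0]) for i in range(len(rows)))
    denom = _log_comb(rows.sum(), c1)

    total = 0.0
    tol = 1e-9

    def recurse(i, remaining, logp):
        nonlocal total
        if i == len(rows) - 1:
            if 0 <= remaining <= rows[i]:
                lp = logp + _log_comb(rows[i], remaining)
                if lp <= logp_obs + tol:
                    total += np.exp(lp - denom)
            return
        tail = rows[i + 1:].sum()
        lo = max(0, remaining - tail)
        hi = min(rows[i], remaining)
        for a in range(lo, hi + 1):
            recurse(i + 1, remaining - a, logp + _log_comb(rows[i], a))

    recurse(0, c1, 0.0)
    return min(1.0, float(total))


def cohens_w(table: np.ndarray) -> float:
    """Effect size w = sqrt(chi-square / N) of a contingency table."""
    table = np.asarray(table, dtype=float)
    n = table.sum()
    if n == 0:
        raise ValueError("all-zero contingency table")
    expected = np.outer(table.sum(axis=1), table.sum(axis=0)) / n
    mask = expected > 0
    chi2 = ((table[mask] - expected[mask]) ** 2 / expected[mask]).sum()
    return float(np.sqrt(chi2 / n))


def compare_frequencies(counts_group1, counts_group2,
                        labels=("group1", "group2")) -> FrequencyComparison:
    """Exact test and effect size for haplogroup composition of two groups.

    ``counts_group*`` map haplogroup -> count (missing haplogroups count 0).
    Rows with zero total in both groups are dropped before testing.
    """
    cats = [h for h in HAPLOGROUPS
            if counts_group1.get(h, 0) + counts_group2.get(h, 0) > 0]
    if not cats:
        raise ValueError("all-zero contingency table")
    tab = pd.DataFrame(
        {labels[0]: [counts_group1.get(h, 0) for h in cats],
         labels[1]: [counts_group2.get(h, 0) for h in cats]},
        index=cats,
    )
    arr = tab.to_numpy()
    p = exact_rx2_test(arr)
    w = cohens_w(arr)
    freq_rows = []
    for gi, g in enumerate(labels):
        n = int(arr[:, gi].sum())
        for h in cats:
            k = int(tab.at[h, g])
            if n > 0:
                lo, hi = binomial_ci(k, n)
            else:
                lo = hi = np.nan
            freq_rows.append({"group": g, "haplogroup": h, "count": k, "n": n,
                              "frequency": k / n if n else np.nan,
                              "ci_low": lo, "ci_high": hi})
    return FrequencyComparison(tab, p, w, pd.DataFrame(freq_rows))
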