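"""Molecular sex determination from length-normalized per-chromosome read counts.

A library from an XY male maps reads to chromosome X at roughly half the
intensity (reads per base) of the autosomes, because the X is present in one
copy; XX females show a 1:1 ratio.  The expected X intensity under the XX
null is obtained by locally weighted (loess) regression of intensity on
chromosome length over the autosomes only (span 0.80), predicted at the X
chromosome's length, with a t-based 95% interval from the residual error.
An individual whose observed X intensity falls inside that interval is
called XX; one whose observed/expected ratio sits in a conservative band
around 0.5 while outside the XX interval is called XY; anything else is
ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import t as t_dist


def chrom_counts(reads_or_counts, layout) -> pd.DataFrame:
    """Per-chromosome mapped-read counts with lengths and intensity.

    ``reads_or_counts`` is either an iterable of read records (counted per
    chromosome) or a DataFrame already holding chrom/count columns.
    ``layout`` gives (name, length) pairs and defines which chromosomes
    exist; MT is excluded (its copy number does not track the karyotype).
    """
    lengths = {str(n): int(l) for n, l in layout if n != "MT"}
    if "X" not in lengths:
        raise ValueError("layout must contain an X chromosome")
    if isinstance(reads_or_counts, pd.DataFrame):
        counts = {str(c): int(k) for c, k in
                  zip(reads_or_counts["chrom"], reads_or_counts["count"])}
    else:
        counts = {}
        for r in reads_or_counts:
            if getattr(r, "is_endogenous", True):
                counts[str(r.chrom)] = counts.get(str(r.chrom), 0) + 1
    rows = []
    for name, length in lengths.items():
        k = counts.get(name, 0)
        if k < 0 or length <= 0:
            raise ValueError("counts must be >= 0 and lengths > 0")
        rows.append({"chrom": name, "length": length, "count": k,
                     "intensity": k / length, "is_x": name == "X"})
    df = pd.DataFrame(rows)
    if df["is_x"].sum() != 1:
        raise ValueError("exactly one X chromosome required")
    return df


def _loess_operator(x: np.ndarray, x0: float, span: float,
                    degree: int) -> np.ndarray:
    """Equivalent-kernel weight vector l(x0): prediction = l(x0) @ y.

    Tricube weights over the ceil(span * n) nearest points, local polynomial
    of the given degree solved by weighted least squares.
    """
    n = len(x)
    k = int(np.ceil(span * n))
    k = min(max(k, degree + 2), n)
    d = np.abs(x - x0)
    h = np.sort(d)[k - 1]
    if h <= 0:
        h = np.finfo(float).eps
    w = np.clip(1.0 - (d / h) ** 3, 0.0, None) ** 3
    # points right at the bandwidth edge get weight 0; guard against an
    # all-zero weight vector on degenerate spacing
    if w.sum() == 0:
        w = (d <= h).astype(float)
    # centre and rescale by the bandwidth: chromosome lengths are in the
    # megabase range and an unscaled cubic design is numerically singular
    design = np.vander((x - x0) / h, degree + 1, increasing=True)
    wd = design * w[:, None]
    beta_op = np.linalg.pinv(design.T @ wd) @ wd.T            # (deg+1, n)
    return beta_op[0]                                         # intercept row


@dataclass
class XXExpectation:
    """Loess-predicted X intensity under the XX null, with a 95% t interval."""
    predicted: float
    se: float
    lower: float
    upper: float
    residual_df: float
    span: float


def loess_expectation(counts: pd.DataFrame, span: float = 0.80,
                      degree: int | None = None,
                      level: float = 0.95) -> XXExpectation:
    """Fit intensity ~ length over autosomes only and predict at the X's length.

    The X chromosome is excluded from the regression.  The residual degrees
    of freedom are the autosome count minus the loess-equivalent parameters
    (trace of the smoother matrix), floored at 2.  With fewer than 10
    autosomes the local polynomial degrades to degree 1 (weighted linear).
    """
    if not 0.0 < span <= 1.0:
        raise ValueError("span must be in (0, 1]")
    auto = counts[~counts["is_x"]]
    if (auto["count"] > 0).sum() < 5:
        raise ValueError("need >= 5 autosomes with nonzero counts")
    x = auto["length"].to_numpy(dtype=float)
    y = auto["intensity"].to_numpy(dtype=float)
    n = len(x)
    if degree is None:
        degree = 2 if n >= 10 else 1

    smoother = np.vstack([_loess_operator(x, xi, span, degree) for xi in x])
    fitted = smoother @ y
    rss = float(((y - fitted) ** 2).sum())
    df = max(n - float(np.trace(smoother)), 2.0)
    s2 = rss / df

    x_len = float(counts.loc[counts["is_x"], "length"].iloc[0])
    l0 = _loess_operator(x, x_len, span, degree)
    predicted = float(l0 @ y)
    # prediction interval: the observed X intensity is a new observation, so
    # its sampling noise (one residual's worth) adds to the curve uncertainty
    se = float(np.sqrt(s2 * (1.0 + l0 @ l0)))
    tcrit = t_dist.ppf(0.5 + level / 2.0, df)
    return XXExpectation(predicted, se, predicted - tcrit * se,
                         predicted + tcrit * se, df, span)


@dataclass
class SexCall:
    x_intensity: float
    expected: float
    lower: float
    upper: float
    ratio: float
    label: str  # "XX" | "XY" | "ambiguous"


XY_RATIO_BAND = (0.35, 0.65)  # conservative band around the 0.5 expectation


def classify_sex(counts: pd.DataFrame, expectation: XXExpectation | None = None,
                 span: float = 0.80, xy_band=XY_RATIO_BAND) -> SexCall:
    """Label an individual XX / XY / ambiguous from its chromosome counts.

    XX when the observed X intensity lies inside the 95% XX interval; XY when
    the observed/expected ratio falls within ``xy_band`` while the intensity
    is outside the XX interval; ambiguous otherwise (boundary cases are never
    forced into a call).
    """
    if counts.loc[~counts["is_x"], "count"].sum() == 0:
        raise ValueError("no autosomal reads")
    if expectation is None:
        expectation = loess_expectation(counts, span=span)
    observed = float(counts.loc[counts["is_x"], "intensity"].iloc[0])
    ratio = observed / expectation.predicted
    if expectation.lower <= observed <= expectation.upper:
        label = "XX"
    elif xy_band[0] <= ratio <= xy_band[1]:
        label = "XY"
    else:
        label = "ambiguous"
    return SexCall(observed, expectation.predicted, expectation.lower,
                   expectation.upper, ratio, label)
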