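"""Model-comparison and reliability statistics.

Covers the summary statistics used to compare the model variants and to
assess repeatability: median absolute error (MedAE) of parameter recovery,
binned signed-error summaries with feasibility envelopes, the
small-sample-corrected Akaike information criterion (AICc), the comparison
of the fitted dot fraction against the Rician noise floor √(π/2)·σ, and
Bland–Altman agreement analysis.

The two-sample Kolmogorov–Smirnov test is implemented directly as the
sup-distance between empirical CDFs with the asymptotic Kolmogorov
p-value, since the comparisons here are always between two finite samples
of ROI or per-truth values.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import special

from .models import PARAM_NAMES

__all__ = [
    "EvaluationSummary",
    "AgreementReport",
    "median_absolute_error",
    "aicc",
    "binned_error_summary",
    "ks_two_sample",
    "fdot_vs_rician_floor",
    "bland_altman",
    "RICIAN_FLOOR_FACTOR",
]

RICIAN_FLOOR_FACTOR = math.sqrt(math.pi / 2.0)


def _to_param_frame(items) -> pd.DataFrame:
    """Lists of TissueParameters / FitResult, 2-D arrays, or DataFrames →
    DataFrame with the canonical parameter columns."""
    if isinstance(items, pd.DataFrame):
        return items
    if isinstance(items, dict):
        return pd.DataFrame(items)
    if len(items) == 0:
        return pd.DataFrame(columns=list(PARAM_NAMES))
    first = items[0]
    if hasattr(first, "estimates"):  # FitResult
        items = [r.estimates for r in items]
        first = items[0] if len(items) else None
    if hasattr(first, "to_array"):
        arr = np.stack([p.to_array() for p in items])
        return pd.DataFrame(arr, columns=list(PARAM_NAMES))
    arr = np.atleast_2d(np.asarray(items, dtype=float))
    return pd.DataFrame(arr, columns=list(PARAM_NAMES)[: arr.shape[1]])


def median_absolute_error(estimates, truths) -> dict:
    """Per-parameter median of |estimate − truth|.

    Robust to the heavy-tailed error distributions that bounded estimators
    produce near their bounds, unlike RMSE.  Inputs may be lists of
    parameter sets, fit results, arrays, or DataFrames with matching
    columns.
    """
    est = _to_param_frame(estimates)
    tru = _to_param_frame(truths)
    if len(est) != len(tru):
        raise ValueError("estimates and truths must have equal length")
    if len(est) == 0:
        raise ValueError("need at least one pair")
    common = [c for c in est.columns if c in tru.columns]
    return {c: float(np.median(np.abs(est[c].to_numpy()
                                      - tru[c].to_numpy())))
            for c in common}


def aicc(rss: float, n_points: int, k: int) -> float:
    """Corrected Akaike information criterion for a least-squares fit:
    n·ln(rss/n) + 2k + 2k(k+1)/(n−k−1)."""
    if n_points <= k + 1:
        raise ValueError("AICc undefined for n_points <= k + 1")
    if rss <= 0:
        raise ValueError("rss must be > 0")
    n = n_points
    return n * math.log(rss / n) + 2 * k + 2 * k * (k + 1) / (n - k - 1)


def binned_error_summary(truths, estimates, n_bins: int = 10,
                         bounds: dict | None = None) -> dict:
    """Median and IQR of the signed error (estimate − truth) in equal-width
    bins of the true value, per parameter.

    ``bounds`` maps parameter name → (low, high) of both the sampled range
    (bin edges) and the estimator box; the returned frames include the
    feasibility envelope (bound − bin center), i.e. the largest error the
    bounded estimator could produce for truths at the bin center.
    Empty bins are reported with NaN summaries, not errors.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    est = _to_param_frame(estimates)
    tru = _to_param_frame(truths)
    if len(est) != len(tru):
        raise ValueError("estimates and truths must have equal length")
    out = {}
    for c in [c for c in est.columns if c in tru.columns]:
        t = tru[c].to_numpy()
        err = est[c].to_numpy() - t
        if bounds and c in bounds:
            lo, hi = bounds[c]
        else:
            lo, hi = float(t.min()), float(t.max())
        edges = np.linspace(lo, hi, n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        which = np.clip(np.digitize(t, edges) - 1, 0, n_bins - 1)
        rows = []
        for i in range(n_bins):
            e = err[which == i]
            if e.size:
                med, q1, q3 = (float(np.median(e)),
                               float(np.percentile(e, 25)),
                               float(np.percentile(e, 75)))
            else:
                med = q1 = q3 = float("nan")
            rows.append({"bin_center": centers[i], "n": int(e.size),
                         "median": med, "q25": q1, "q75": q3,
                         "envelope_low": lo - centers[i],
                         "envelope_high": hi - centers[i]})
        out[c] = pd.DataFrame(rows)
    return out


def ks_two_sample(a, b):
    """Two-sample Kolmogorov–Smirnov statistic and asymptotic p-value.

    D = sup |F_a − F_b| over the pooled sample;
    p = Q_KS(D·√(nm/(n+m))) via the Kolmogorov distribution.
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    n, m = a.size, b.size
    if n == 0 or m == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, pooled, side="right") / n
    cdf_b = np.searchsorted(b, pooled, side="right") / m
    d = float(np.max(np.abs(cdf_a - cdf_b)))
    en = math.sqrt(n * m / (n + m))
    p = float(special.kolmogorov(en * d))
    return d, min(max(p, 0.0), 1.0)


@dataclass(frozen=True)
class AgreementReport:
    """Paired-sample agreement summary."""

    mean_diff: float
    sd_diff: float
    loa_low: float           # mean_diff − 1.96·sd
    loa_high: float          # mean_diff + 1.96·sd
    pearson_r: float
    ks_stat: float
    ks_p: float
    n: int
    means: np.ndarray = None   # (a+b)/2, for Bland–Altman plotting
    diffs: np.ndarray = None   # a − b


def _agreement(a, b) -> AgreementReport:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired lists must have equal length")
    d = a - b
    mean = float(d.mean())
    sd = float(d.std(ddof=1)) if d.size > 1 else 0.0
    if a.size > 1 and a.std() > 0 and b.std() > 0:
        r = float(np.corrcoef(a, b)[0, 1])
    else:
        r = float("nan")
    ks_d, ks_p = ks_two_sample(a, b)
    return AgreementReport(mean, sd, mean - 1.96 * sd, mean + 1.96 * sd,
                           r, ks_d, ks_p, a.size, 0.5 * (a + b), d)


def fdot_vs_rician_floor(f_dot_values, sigma_values) -> AgreementReport:
    """Compare fitted dot fractions against the Rician floor √(π/2)·σ.

    When the dot compartment merely soaks up the un-modelled noise floor,
    the two quantities are strongly correlated and similarly distributed —
    the diagnostic that the dot fraction is a noise artifact rather than a
    tissue compartment.
    """
    f_dot_values = np.asarray(f_dot_values, dtype=float)
    floor = RICIAN_FLOOR_FACTOR * np.asarray(sigma_values, dtype=float)
    return _agreement(f_dot_values, floor)


def bland_altman(values_a, values_b) -> AgreementReport:
    """Bland–Altman agreement: mean difference and 95% limits of agreement
    (mean ± 1.96·SD) of paired measurements, with per-pair means retained
    for plotting."""
    a = np.asarray(values_a, dtype=float)
    if a.size < 2:
        raise ValueError("need at least two pairs")
    return _agreement(values_a, values_b)


@dataclass
class EvaluationSummary:
    """Per-model recovery summary over a simulated dataset."""

    medae: dict
    binned: dict
    mean_aicc: float
    sd_aicc: float
    bound_hit_rates: dict

    @classmethod
    def from_fits(cls, fits, truths, n_bins: int = 10,
                  bounds: dict | None = None) -> "EvaluationSummary":
        medae = median_absolute_error(fits, truths)
        binned = binned_error_summary(truths, fits, n_bins=n_bins,
                                      bounds=bounds)
        ics = np.array([r.aicc for r in fits], dtype=float)
        ics = ics[np.isfinite(ics)]
        rates: dict = {}
        for r in fits:
            for name in r.bound_hits:
                rates[name] = rates.get(name, 0) + 1
        rates = {k: v / len(fits) for k, v in rates.items()}
        return cls(medae, binned,
                   float(ics.mean()) if ics.size else float("nan"),
                   float(ics.std(ddof=1)) if ics.size > 1 else float("nan"),
                   rates)
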