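"""Null-model fitting and per-combination enrichment statistics.

For every combination, the shuffled values of S (overlapping base pairs)
and N (overlap windows) are modelled with a Negative Binomial fitted by the
method of moments — from the empirical mean m and variance v of the
shuffles, p = m / v and r = m^2 / (v - m), requiring overdispersion
(v > m).  Moment fitting is preferred over maximum likelihood for
robustness.  Enrichment p-values are upper-tail, P(X >= s_obs).

Companions: an empirical p-value with an add-one correction (never zero),
and a Beta fit of S / scale where the scale is the total bp of the analysed
(sub-)genome — a useful approximation to the underlying Beta-Binomial, but
imprecise below thousands of shuffles and flagged as such.

Fit quality is screened with Cramér's V between the binned shuffle
histogram and the fitted distribution; poor fits arise mainly when a
combination is too rare in the shuffles, in which case p-values tend to be
conservative while fold changes stay accurate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy import stats

from .overlap_core import Combination
from .shuffler import ShuffleSamples

__all__ = [
    "NegBinParams",
    "BetaParams",
    "FitDiagnostics",
    "CombinationStats",
    "fit_negbin_moments",
    "negbin_pvalue",
    "empirical_pvalue",
    "fold_change",
    "cramers_v_fit",
    "fit_beta_pvalue",
    "summarize_combination",
    "merge_runs",
]


@dataclass(frozen=True)
class NegBinParams:
    """NB(r, p) with mean r(1-p)/p and variance mean/p (scipy's convention).

    ``degenerate`` marks samples the NB cannot represent (variance <= mean
    or all zeros); downstream p-values then fall back as documented.
    """

    r: float
    p: float
    mean: float
    variance: float
    degenerate: bool = False
    reason: str | None = None


@dataclass(frozen=True)
class BetaParams:
    a: float
    b: float
    scale: float
    degenerate: bool = False
    low_confidence: bool = False
    reason: str | None = None


Verdict = Literal["good", "poor", "untestable"]


@dataclass(frozen=True)
class FitDiagnostics:
    cramers_v: float | None
    n_bins: int
    verdict: Verdict


@dataclass
class CombinationStats:
    """All per-combination outputs assembled into one record."""

    combination: Combination
    S_obs: int
    N_obs: int
    S_exp_mean: float
    S_exp_sd: float
    log2_fold_change: float
    p_nb_S: float
    p_nb_N: float
    p_empirical_S: float
    p_beta_S: float | None
    nb_params_S: NegBinParams
    beta_params_S: BetaParams | None
    fit: FitDiagnostics


def fit_negbin_moments(samples: Sequence[int] | np.ndarray) -> NegBinParams:
    """Method-of-moments Negative Binomial fit.

    p = mean/variance, r = mean^2/(variance - mean); requires at least two
    samples and overdispersion.  Underdispersed or constant samples return
    a degenerate-flagged result (the NB is undefined there), and all-zero
    samples are flagged untestable — typical of combinations too rare in
    the shuffles.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 2:
        raise ValueError("need at least two samples to fit moments")
    m = float(x.mean())
    v = float(x.var(ddof=1))
    if m == 0.0:
        return NegBinParams(math.nan, math.nan, m, v, degenerate=True, reason="all_zero")
    if v <= m:
        return NegBinParams(math.nan, math.nan, m, v, degenerate=True, reason="underdispersed")
    p = m / v
    r = m * m / (v - m)
    return NegBinParams(r, p, m, v)


def negbin_pvalue(params: NegBinParams, s_obs: int) -> tuple[float, bool]:
    """Upper-tail P(X >= s_obs) under the fitted NB.

    Returns ``(p, fallback)``: for degenerate parameters a Poisson(mean)
    tail is used instead and flagged — the NB collapses to a Poisson as the
    variance approaches the mean, and the flag tells the caller the
    combination's dispersion could not be modelled.
    """
    if s_obs <= 0:
        return 1.0, params.degenerate
    if params.degenerate:
        if params.mean == 0.0 or math.isnan(params.mean):
            return (0.0 if s_obs > 0 else 1.0), True
        return float(stats.poisson.sf(s_obs - 1, params.mean)), True
    return float(stats.nbinom.sf(s_obs - 1, params.r, params.p)), False


def empirical_pvalue(samples: Sequence[int] | np.ndarray, s_obs: float) -> float:
    """Add-one empirical p-value (1 + #{samples >= s_obs}) / (n + 1)."""
    x = np.asarray(samples)
    if x.size == 0:
        raise ValueError("no samples")
    return float((1 + int((x >= s_obs).sum())) / (x.size + 1))


def fold_change(s_obs: float, s_exp_mean: float, pseudocount: float = 1.0) -> float:
    """log2 enrichment m(gamma) = log2(S_obs / S_exp).

    When either term is zero a pseudo-count (default 1 bp) is added to both
    so the fold change stays finite; otherwise the plain ratio is used.
    """
    if s_obs < 0 or s_exp_mean < 0:
        raise ValueError("S values must be non-negative")
    if s_obs == 0.0 or s_exp_mean == 0.0:
        return math.log2((s_obs + pseudocount) / (s_exp_mean + pseudocount))
    return math.log2(s_obs / s_exp_mean)


def cramers_v_fit(
    samples: Sequence[int] | np.ndarray,
    params: NegBinParams,
    threshold: float = 0.25,
    min_expected: float = 5.0,
    max_bins: int = 10,
) -> FitDiagnostics:
    """Goodness of fit of the NB via Cramér's V on binned counts.

    Bin edges are quantiles of the fitted NB chosen so each bin's expected
    count is at least ``min_expected``; V = sqrt(chi2 / (n * (b - 1))) for
    b bins.  Verdict 'good' iff V < threshold; fewer than 3 usable bins or
    degenerate parameters give 'untestable'.
    """
    x = np.asarray(samples, dtype=float)
    if params.degenerate or x.size < 20 or np.unique(x).size < 3:
        return FitDiagnostics(None, 0, "untestable")
    n = x.size
    n_bins = int(min(max_bins, n // min_expected))
    if n_bins < 3:
        return FitDiagnostics(None, 0, "untestable")
    qs = np.linspace(0, 1, n_bins + 1)[1:-1]
    inner = np.unique(stats.nbinom.ppf(qs, params.r, params.p))
    edges = np.concatenate(([-0.5], inner + 0.5, [np.inf]))
    if len(edges) < 4:  # < 3 distinct bins after deduplication
        return FitDiagnostics(None, 0, "untestable")
    obs, _ = np.histogram(x, bins=edges)
    cdf = stats.nbinom.cdf(edges, params.r, params.p)
    exp = np.diff(cdf) * n
    ok = exp > 0
    chi2 = float(((obs[ok] - exp[ok]) ** 2 / exp[ok]).sum())
    b = int(ok.sum())
    v = math.sqrt(chi2 / (n * (b - 1)))
    return FitDiagnostics(v, b, "good" if v < threshold else "poor")


def fit_beta_pvalue(
    samples: Sequence[int] | np.ndarray,
    s_obs: float,
    scale: float,
    low_confidence_below: int = 1000,
) -> tuple[BetaParams, float | None]:
    """Moment fit of a Beta to samples/scale; upper-tail p at s_obs/scale.

    ``scale`` is the total bp of the analysed (sub-)genome.  With only
    hundreds of shuffles the tail fit is imprecise, so the result is
    flagged low-confidence below ``low_confidence_below`` samples.
    """
    x = np.asarray(samples, dtype=float)
    if scale <= 0:
        raise ValueError("scale must be positive")
    if x.size and x.max() > scale:
        raise ValueError("samples exceed the scale")
    frac = x / scale
    m = float(frac.mean())
    v = float(frac.var(ddof=1)) if frac.size > 1 else 0.0
    low_conf = x.size < low_confidence_below
    if v == 0.0 or m <= 0.0 or m >= 1.0 or v >= m * (1 - m):
        return (
            BetaParams(math.nan, math.nan, scale, degenerate=True,
                       low_confidence=low_conf, reason="degenerate_moments"),
            None,
        )
    common = m * (1 - m) / v - 1
    a = m * common
    b = (1 - m) * common
    if s_obs <= 0:
        return BetaParams(a, b, scale, low_confidence=low_conf), 1.0
    p = float(stats.beta.sf(s_obs / scale, a, b))
    return BetaParams(a, b, scale, low_confidence=low_conf), p


def summarize_combination(
    combination: Combination,
    S_samples: Sequence[int] | np.ndarray,
    N_samples: Sequence[int] | np.ndarray,
    S_obs: int,
    N_obs: int,
    scale: float,
    fit_threshold: float = 0.25,
) -> CombinationStats:
    """Assemble all statistics for one combination; degenerate fits are
    flagged, never raised."""
    S_samples = np.asarray(S_samples, dtype=np.int64)
    N_samples = np.asarray(N_samples, dtype=np.int64)
    if S_samples.shape != N_samples.shape:
        raise ValueError("S and N sample arrays differ in length")
    nb_S = fit_negbin_moments(S_samples)
    nb_N = fit_negbin_moments(N_samples)
    p_nb_S, _ = negbin_pvalue(nb_S, S_obs)
    p_nb_N, _ = negbin_pvalue(nb_N, N_obs)
    beta_S, p_beta_S = fit_beta_pvalue(S_samples, S_obs, scale)
    mean_S = float(S_samples.mean())
    return CombinationStats(
        combination=combination,
        S_obs=int(S_obs),
        N_obs=int(N_obs),
        S_exp_mean=mean_S,
        S_exp_sd=float(S_samples.std(ddof=1)) if S_samples.size > 1 else 0.0,
        log2_fold_change=fold_change(S_obs, mean_S),
        p_nb_S=p_nb_S,
        p_nb_N=p_nb_N,
        p_empirical_S=empirical_pvalue(S_samples, S_obs),
        p_beta_S=p_beta_S,
        nb_params_S=nb_S,
        beta_params_S=beta_S,
        fit=cramers_v_fit(S_samples, nb_S, threshold=fit_threshold),
    )


def merge_runs(runs: Sequence[ShuffleSamples]) -> ShuffleSamples:
    """Concatenate independent Monte Carlo runs into one superbatch.

    Sample arrays are concatenated per combination, padding with zeros for
    combinations absent from a run (absent means never observed there).
    Fit diagnostics must be recomputed by the caller and are conventionally
    reported as not assessed for superbatch merges.
    """
    if len(runs) < 2:
        raise ValueError("need at least two runs to merge")
    first = runs[0]
    for run in runs[1:]:
        if run.set_names != first.set_names:
            raise ValueError("runs have different set lists")
        if run.mode != first.mode:
            raise ValueError("runs have different counting modes")
    total = sum(r.n_shuffles for r in runs)
    merged = ShuffleSamples(list(first.set_names), first.mode, total)
    combos: list[Combination] = []
    seen = set()
    for run in runs:
        for c in run.combinations():
            if c not in seen:
                seen.add(c)
                combos.append(c)
    for c in combos:
        merged.S[c] = np.concatenate(
            [r.S.get(c, np.zeros(r.n_shuffles, dtype=np.int64)) for r in runs]
        )
        merged.N[c] = np.concatenate(
            [r.N.get(c, np.zeros(r.n_shuffles, dtype=np.int64)) for r in runs]
        )
    return merged
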