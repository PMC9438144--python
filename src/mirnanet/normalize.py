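"""Count normalization: TMM scaling factors, log-CPM and precision weights.

The normalization pipeline mirrors the standard small RNA-seq workflow:
trimmed-mean-of-M-values (TMM) scaling factors absorb composition bias
between libraries, counts are transformed to log2 counts-per-million with a
small prior, and per-observation precision weights are derived from a lowess
fit of the square-root residual standard deviation against mean log-count
(the mean-variance trend), so downstream linear modelling can treat the
log-scale data as approximately homoscedastic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata
from statsmodels.nonparametric.smoothers_lowess import lowess

from .io import CountMatrix


def _quantile_factor(counts: np.ndarray, lib_sizes: np.ndarray, p: float = 0.75) -> np.ndarray:
    return np.quantile(counts, p, axis=0) / lib_sizes


def _tmm_pair(
    obs: np.ndarray,
    ref: np.ndarray,
    n_obs: float,
    n_ref: float,
    trim_m: float,
    trim_a: float,
    a_cutoff: float = -1e10,
) -> float:
    """Trimmed, precision-weighted mean of M-values of one sample vs the reference.

    Features with zero counts in either library drop out (their log-ratio is
    undefined); the remaining log-ratios are doubly trimmed — ``trim_m`` on
    each tail of the M distribution and ``trim_a`` on each tail of the
    average-abundance (A) distribution — and averaged with inverse
    asymptotic-variance weights.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        log_r = np.log2((obs / n_obs) / (ref / n_ref))
        abs_e = (np.log2(obs / n_obs) + np.log2(ref / n_ref)) / 2.0
        v = (n_obs - obs) / (n_obs * obs) + (n_ref - ref) / (n_ref * ref)
    keep = np.isfinite(log_r) & np.isfinite(abs_e) & (abs_e > a_cutoff)
    log_r, abs_e, v = log_r[keep], abs_e[keep], v[keep]
    if log_r.size == 0 or np.max(np.abs(log_r)) < 1e-6:
        return 1.0
    n = log_r.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rank_m = rankdata(log_r)
    rank_a = rankdata(abs_e)
    sel = (rank_m >= lo_m) & (rank_m <= hi_m) & (rank_a >= lo_a) & (rank_a <= hi_a)
    if not np.any(sel):
        return 1.0
    f = np.sum(log_r[sel] / v[sel]) / np.sum(1.0 / v[sel])
    return float(2.0 ** f)


def compute_tmm_factors(
    counts: CountMatrix | np.ndarray,
    ref_sample: int | None = None,
    trim_m: float = 0.30,
    trim_a: float = 0.05,
) -> np.ndarray:
    """Per-sample TMM scaling factors, rescaled to geometric mean 1.

    Parameters
    ----------
    counts
        Count matrix (features x samples).
    ref_sample
        Column index of the reference library; by default the sample whose
        75th-percentile count fraction is closest to the across-sample mean.
    trim_m, trim_a
        Two-sided trim fractions on the M-value and A-value distributions.
    """
    mat = counts.counts.astype(float) if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    if mat.ndim != 2:
        raise ValueError("counts must be 2-D")
    lib = mat.sum(axis=0)
    if np.any(lib <= 0):
        raise ValueError("all-zero sample: TMM factors undefined")
    if ref_sample is None:
        f75 = _quantile_factor(mat, lib)
        ref_sample = int(np.argmin(np.abs(f75 - f75.mean())))
    factors = np.array(
        [
            _tmm_pair(mat[:, j], mat[:, ref_sample], lib[j], lib[ref_sample], trim_m, trim_a)
            for j in range(mat.shape[1])
        ]
    )
    factors /= np.exp(np.mean(np.log(factors)))
    return factors


def log_cpm(
    counts: CountMatrix | np.ndarray,
    factors: np.ndarray | None = None,
    prior_count: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """log2 counts-per-million with a prior, plus linear per-million values.

    Returns ``(logcpm, per_million)`` where
    ``logcpm = log2((count + prior) / (effective_lib + 2*prior) * 1e6)`` and
    ``per_million = count / effective_lib * 1e6``.  The effective library
    size is the raw library size times its TMM factor.  For short features
    counted whole there is no meaningful length term, so the per-million
    column is the reportable abundance unit.
    """
    mat = counts.counts.astype(float) if isinstance(counts, CountMatrix) else np.asarray(counts, dtype=float)
    lib = mat.sum(axis=0)
    if factors is not None:
        lib = lib * np.asarray(factors, dtype=float)
    logcpm = np.log2((mat + prior_count) / (lib + 2.0 * prior_count) * 1e6)
    with np.errstate(divide="ignore"):
        per_million = mat / lib * 1e6
    return logcpm, per_million


def voom_weights(
    logcpm: np.ndarray,
    design: np.ndarray,
    lib_sizes: np.ndarray,
    span: float = 0.5,
) -> np.ndarray:
    """Per-observation precision weights from the mean-variance trend.

    For each feature an unweighted least-squares fit on ``design`` gives a
    residual standard deviation; a lowess curve of sqrt(sd) versus mean
    log2-count is interpolated at each observation's fitted log2-count and
    the weight is the inverse fourth power of the interpolated sqrt-sd.

    Parameters
    ----------
    logcpm : (features, samples) log2-CPM matrix
    design : (samples, p) design matrix with >= 2 residual df
    lib_sizes : effective library sizes used to map CPM back to counts
    span : lowess smoothing fraction
    """
    y = np.asarray(logcpm, dtype=float)
    x = np.asarray(design, dtype=float)
    n, p = x.shape
    if y.shape[1] != n:
        raise ValueError("design rows must match samples")
    df_resid = n - np.linalg.matrix_rank(x)
    if df_resid < 2:
        raise ValueError("degenerate design: need >= 2 residual degrees of freedom")

    pinv = np.linalg.pinv(x)
    beta = y @ pinv.T  # (G, p)
    fitted = beta @ x.T  # (G, n)
    resid = y - fitted
    sigma = np.sqrt(np.sum(resid**2, axis=1) / df_resid)

    # mean log2 count per feature (shift CPM back to the count scale)
    mean_log_count = y.mean(axis=1) + np.mean(np.log2(lib_sizes + 1.0)) - np.log2(1e6)
    sqrt_sd = np.sqrt(sigma)

    order = np.argsort(mean_log_count, kind="stable")
    trend = lowess(sqrt_sd[order], mean_log_count[order], frac=span, return_sorted=True)
    tx, ty = trend[:, 0], trend[:, 1]
    # collapse duplicate x for interpolation
    ux, idx = np.unique(tx, return_index=True)
    uy = ty[idx]

    fitted_log_count = fitted + (np.log2(lib_sizes + 1.0) - np.log2(1e6))[None, :]
    interp = np.interp(fitted_log_count, ux, uy)
    interp = np.clip(interp, max(1e-6, uy.min() * 1e-3), None)
    weights = interp**-4
    if not np.all(np.isfinite(weights)) or np.any(weights <= 0):
        raise ValueError("non-finite precision weights")
    return weights


@dataclass
class NormalizedExpression:
    """TMM-normalized, voom-transformed expression with precision weights."""

    feature_ids: list[str]
    sample_ids: list[str]
    logcpm: np.ndarray       # (G, n)
    per_million: np.ndarray  # (G, n) linear per-million abundances
    lib_sizes: np.ndarray    # raw library sizes
    factors: np.ndarray      # TMM factors, geometric mean 1
    weights: np.ndarray      # (G, n) precision weights

    def __post_init__(self) -> None:
        if np.any(self.factors <= 0):
            raise ValueError("scaling factors must be positive")
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")


def normalize(counts: CountMatrix, design: np.ndarray, prior_count: float = 0.5) -> NormalizedExpression:
    """Run TMM + log-CPM + precision-weight estimation on a count matrix."""
    factors = compute_tmm_factors(counts)
    logcpm, per_million = log_cpm(counts, factors, prior_count=prior_count)
    lib = counts.library_sizes()
    eff_lib = lib * factors
    weights = voom_weights(logcpm, design, eff_lib)
    return NormalizedExpression(
        feature_ids=list(counts.feature_ids),
        sample_ids=list(counts.sample_ids),
        logcpm=logcpm,
        per_million=per_million,
        lib_sizes=lib,
        factors=factors,
        weights=weights,
    )
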