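"""Moderated differential expression for small RNA-seq count data.

Per-feature weighted least squares on voom-transformed expression, with
empirical-Bayes variance shrinkage: the posterior variance is
``s2_post = (d0*s0^2 + d*s^2) / (d0 + d)`` where the prior degrees of freedom
``d0`` and prior variance ``s0^2`` are estimated by the method of moments on
the log residual variances (a scaled-F / log-chi-square moment fit).  The
moderated t-statistic has ``d0 + d`` degrees of freedom.

The DE filter used throughout is |signed FC| > 1.2 together with raw
p < 0.05 (both strict); Benjamini-Hochberg adjusted p-values are reported
alongside.  DE lists are prioritized by "average rank": the mean of a
feature's rank by |FC| (descending) and by p-value (ascending).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.special import digamma, polygamma
from scipy.stats import rankdata, t as t_dist
from statsmodels.stats.multitest import multipletests

from .io import StudyDesign
from .normalize import NormalizedExpression

CONTRASTS = ("interictal_vs_healthy", "ictal_vs_interictal", "ictal_vs_healthy")

FC_THRESHOLD = 1.2
P_THRESHOLD = 0.05


# ---------------------------------------------------------------------------
# signed fold change
# ---------------------------------------------------------------------------

def signed_fc(log2fc):
    """Signed linear fold change: 2**x for x >= 0, -2**(-x) otherwise.

    The signed convention always has |FC| >= 1; FC = 1 corresponds to no
    change, FC = -2.4 to a 2.4-fold decrease.
    """
    x = np.asarray(log2fc, dtype=float)
    out = np.where(x >= 0, 2.0**x, -(2.0 ** (-x)))
    return out if out.ndim else float(out)


def log2_from_signed_fc(fc):
    """Inverse of :func:`signed_fc`."""
    f = np.asarray(fc, dtype=float)
    if np.any(np.abs(f) < 1.0):
        raise ValueError("signed fold changes have |FC| >= 1")
    out = np.where(f >= 0, np.log2(np.abs(f)), -np.log2(np.abs(f)))
    return out if out.ndim else float(out)


def classify_direction(fc_signed):
    """'up' for positive signed FC, 'down' for negative."""
    f = np.asarray(fc_signed, dtype=float)
    out = np.where(f >= 1.0, "up", np.where(f <= -1.0, "down", "none"))
    return out if out.ndim else str(out)


# ---------------------------------------------------------------------------
# multiple testing
# ---------------------------------------------------------------------------

def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (input order preserved)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# empirical-Bayes variance shrinkage
# ---------------------------------------------------------------------------

def trigamma_inverse(x: float) -> float:
    """Solve trigamma(y) = x by Newton iteration."""
    if x > 1e7:
        return 1.0 / np.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(50):
        tri = polygamma(1, y)
        dif = tri * (1.0 - tri / x) / polygamma(2, y)
        y = y + dif
        if -dif / y < 1e-8:
            break
    return float(y)


def squeeze_var(s2: np.ndarray, df: float, prior_df: float | None = None) -> tuple[float, float, np.ndarray]:
    """Shrink per-feature variances toward a common prior.

    Returns ``(d0, s0_sq, s2_post)``.  The prior is fitted by the method of
    moments on log variances: if z = log(s2) then under a scaled-F model
    E[z] and Var[z] involve digamma/trigamma terms of df/2 and d0/2, which
    are inverted for (d0, s0_sq).  ``prior_df`` overrides the estimated d0
    (0 recovers the ordinary per-feature variances, inf the common value).
    """
    s2 = np.asarray(s2, dtype=float)
    s2_safe = np.maximum(s2, 1e-300)
    z = np.log(s2_safe)
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(np.mean(e))
    n = len(e)
    evar = float(np.var(e, ddof=1)) - float(polygamma(1, df / 2.0)) if n > 1 else 0.0

    if evar > 0:
        d0_est = 2.0 * trigamma_inverse(evar)
    else:
        d0_est = np.inf

    d0 = d0_est if prior_df is None else float(prior_df)

    if np.isfinite(d0) and d0 > 0:
        s0_sq = float(np.exp(emean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    elif d0 == 0:
        s0_sq = float(np.exp(emean))
        s2_post = s2.copy()
    else:  # infinite prior df: all variances equal the common value
        s0_sq = float(np.exp(emean))
        s2_post = np.full_like(s2, s0_sq)
    return d0, s0_sq, s2_post


# ---------------------------------------------------------------------------
# weighted least squares, batched over features
# ---------------------------------------------------------------------------

def _batched_wls(y: np.ndarray, x: np.ndarray, w: np.ndarray):
    """Per-feature WLS of y (G, n) on x (n, p) with weights w (G, n).

    Returns (beta (G, p), xtx_inv (G, p, p), s2 (G,), df_resid).
    """
    n, p = x.shape
    xtwx = np.einsum("ni,gn,nk->gik", x, w, x)
    xtwy = np.einsum("ni,gn->gi", x, w * y)
    xtx_inv = np.linalg.inv(xtwx)
    beta = np.einsum("gik,gk->gi", xtx_inv, xtwy)
    fitted = beta @ x.T
    resid = y - fitted
    df_resid = n - p
    if df_resid < 1:
        raise ValueError("no residual degrees of freedom")
    s2 = np.sum(w * resid**2, axis=1) / df_resid
    return beta, xtx_inv, s2, df_resid


def moderated_fit(
    y: np.ndarray,
    x: np.ndarray,
    w: np.ndarray,
    contrast_vec: np.ndarray,
    prior_df: float | None = None,
):
    """Moderated t-test for one contrast over all features.

    Returns a dict of arrays: log2fc, t, p, df_total, s2_post.
    """
    beta, xtx_inv, s2, df_resid = _batched_wls(y, x, w)
    d0, s0_sq, s2_post = squeeze_var(s2, df_resid, prior_df=prior_df)
    c = np.asarray(contrast_vec, dtype=float)
    log2fc = beta @ c
    unscaled = np.einsum("i,gik,k->g", c, xtx_inv, c)
    se = np.sqrt(s2_post * unscaled)
    t_stat = log2fc / se
    df_total = (d0 + df_resid) if np.isfinite(d0) else np.inf
    if np.isfinite(df_total):
        p = 2.0 * t_dist.sf(np.abs(t_stat), df_total)
    else:
        from scipy.stats import norm

        p = 2.0 * norm.sf(np.abs(t_stat))
    return {"log2fc": log2fc, "t": t_stat, "p": p, "df_total": df_total, "s2_post": s2_post, "d0": d0, "s0_sq": s0_sq}


# ---------------------------------------------------------------------------
# contrast fitting on a study design
# ---------------------------------------------------------------------------

def _two_group_fit(expr: NormalizedExpression, case: list[str], control: list[str], prior_df):
    idx = {s: j for j, s in enumerate(expr.sample_ids)}
    cols = [idx[s] for s in control] + [idx[s] for s in case]
    y = expr.logcpm[:, cols]
    w = expr.weights[:, cols]
    group = np.array([0] * len(control) + [1] * len(case), dtype=float)
    x = np.column_stack([np.ones_like(group), group])
    return moderated_fit(y, x, w, np.array([0.0, 1.0]), prior_df=prior_df)


def _paired_fit(expr: NormalizedExpression, design: StudyDesign, prior_df):
    pairs = design.paired_samples()
    if len(pairs) < 2:
        raise ValueError("paired contrast needs >= 2 patients with both samples")
    idx = {s: j for j, s in enumerate(expr.sample_ids)}
    i_cols = [idx[s] for _, s, _ in pairs]
    r_cols = [idx[s] for _, _, s in pairs]
    diff = expr.logcpm[:, i_cols] - expr.logcpm[:, r_cols]
    # variance of a difference adds; combine precision weights accordingly
    w = 1.0 / (1.0 / expr.weights[:, i_cols] + 1.0 / expr.weights[:, r_cols])
    x = np.ones((diff.shape[1], 1))
    return moderated_fit(diff, x, w, np.array([1.0]), prior_df=prior_df)


def fit_moderated_de(
    expr: NormalizedExpression,
    design: StudyDesign,
    contrast: str,
    prior_df: float | None = None,
    rank_scope: str = "all_tested",
) -> pd.DataFrame:
    """Fit one contrast and return the full per-feature DE table.

    ``ictal_vs_interictal`` is fit on within-patient differences of
    normalized log-expression (paired moderated t); the two contrasts
    against healthy controls are unpaired two-group fits.
    """
    if contrast not in CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}; expected one of {CONTRASTS}")
    if contrast == "ictal_vs_interictal":
        res = _paired_fit(expr, design, prior_df)
    else:
        case_group, control_group = contrast.split("_vs_")
        case = design.samples_in(case_group)
        control = design.samples_in(control_group)
        if len(case) < 2 or len(control) < 2:
            raise ValueError(f"contrast {contrast}: need >= 2 samples per side")
        res = _two_group_fit(expr, case, control, prior_df)

    fc = signed_fc(res["log2fc"])
    table = pd.DataFrame(
        {
            "feature_id": expr.feature_ids,
            "log2fc": res["log2fc"],
            "fc_signed": fc,
            "t": res["t"],
            "p_raw": res["p"],
            "p_adj_bh": bh_adjust(res["p"]),
            "direction": classify_direction(fc),
        }
    )
    table["avg_rank"] = rank_by_fc_and_p(table) if rank_scope == "all_tested" else np.nan
    return table


# ---------------------------------------------------------------------------
# DE filter and average-rank prioritization
# ---------------------------------------------------------------------------

def filter_de(de: pd.DataFrame, fc_thresh: float = FC_THRESHOLD, p_thresh: float = P_THRESHOLD) -> pd.DataFrame:
    """Keep features with |signed FC| strictly above ``fc_thresh`` and raw
    p strictly below ``p_thresh``."""
    if fc_thresh <= 0 or p_thresh <= 0:
        raise ValueError("thresholds must be positive")
    keep = (de["fc_signed"].abs() > fc_thresh) & (de["p_raw"] < p_thresh)
    return de.loc[keep].copy()


def count_directions(de: pd.DataFrame) -> tuple[int, int]:
    """(n_up, n_down) by the sign of the signed fold change."""
    d = classify_direction(de["fc_signed"].to_numpy())
    return int(np.sum(d == "up")), int(np.sum(d == "down"))


def rank_by_fc_and_p(de: pd.DataFrame) -> np.ndarray:
    """Average of the |FC|-descending rank and the p-ascending rank.

    Ties receive fractional (average) ranks in both orderings.
    """
    if len(de) == 0:
        raise ValueError("empty DE table")
    rank_fc = rankdata(-de["fc_signed"].abs().to_numpy())
    rank_p = rankdata(de["p_raw"].to_numpy())
    return (rank_fc + rank_p) / 2.0


def average_rank(
    de: pd.DataFrame,
    scope: str = "all_tested",
    fc_thresh: float = FC_THRESHOLD,
    p_thresh: float = P_THRESHOLD,
) -> pd.DataFrame:
    """Return the DE subset sorted ascending by average rank.

    ``scope`` controls the ranking universe: ``all_tested`` ranks over every
    tested feature before filtering (so published ranks can exceed the DE
    list length), ``de_only`` ranks within the filtered subset.
    """
    if len(de) == 0:
        raise ValueError("empty DE table")
    if scope not in ("all_tested", "de_only"):
        raise ValueError("scope must be 'all_tested' or 'de_only'")
    if scope == "all_tested":
        ranked = de.copy()
        ranked["avg_rank"] = rank_by_fc_and_p(ranked)
        subset = filter_de(ranked, fc_thresh, p_thresh)
    else:
        subset = filter_de(de, fc_thresh, p_thresh)
        if len(subset) == 0:
            return subset.assign(avg_rank=pd.Series(dtype=float))
        subset = subset.copy()
        subset["avg_rank"] = rank_by_fc_and_p(subset)
    return subset.sort_values(["avg_rank", "feature_id"], kind="stable").reset_index(drop=True)
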