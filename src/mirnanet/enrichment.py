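"""Gene-set overrepresentation analysis with a term-specificity filter.

One-sided hypergeometric (Fisher exact) overrepresentation test per term
with Benjamini-Hochberg FDR across terms.  Terms may carry an annotation
"frequency" — the proportion of gene products annotated to the term — and a
specificity filter keeps only terms with frequency strictly below a cutoff
(default 0.15), discarding overly general terms.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .de import bh_adjust
from .io import GeneSetCollection

logger = logging.getLogger(__name__)

FREQ_CUTOFF = 0.15
ORA_ALPHA = 0.01


def hypergeom_p(k: int, K: int, n: int, N: int) -> float:
    """Upper-tail P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the term size within the universe, n the query
    size, k the observed overlap.
    """
    if not (0 <= k <= min(n, K) <= N) or n > N or K > N or min(k, K, n, N) < 0:
        raise ValueError(f"inconsistent counts k={k}, K={K}, n={n}, N={N}")
    return float(hypergeom.sf(k - 1, N, K, n))


def run_ora(
    query: set[str] | list[str],
    universe: set[str] | list[str],
    collection: GeneSetCollection,
    alpha: float = ORA_ALPHA,
) -> pd.DataFrame:
    """Overrepresentation of ``query`` within each term of ``collection``.

    Term memberships are intersected with the universe before testing; the
    query must be a subset of the universe.  Returns one row per term with
    overlap counts, the hypergeometric p, BH FDR, the term's annotation
    frequency (if any) and the specificity flag.  ``significant`` marks
    terms with raw p below ``alpha``.
    """
    query_set = set(query)
    universe_set = set(universe)
    if not query_set:
        raise ValueError("empty query gene list")
    if not query_set <= universe_set:
        raise ValueError("query genes must be a subset of the universe")
    N = len(universe_set)
    n = len(query_set)
    rows = []
    for gs in collection:
        members = set(gs.members) & universe_set
        K = len(members)
        k = len(members & query_set)
        p = hypergeom_p(k, K, n, N) if K > 0 else 1.0
        rows.append(
            {
                "term_id": gs.term_id,
                "term_name": gs.term_name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_hyper": p,
                "frequency": gs.frequency if gs.frequency is not None else np.nan,
            }
        )
    table = pd.DataFrame(rows)
    table["fdr_bh"] = bh_adjust(table["p_hyper"].to_numpy())
    table["significant"] = table["p_hyper"] < alpha
    table["specific"] = table["frequency"] < FREQ_CUTOFF  # NaN compares False
    return table.sort_values(["p_hyper", "term_id"], kind="stable").reset_index(drop=True)


def specificity_filter(table: pd.DataFrame, cutoff: float = FREQ_CUTOFF) -> pd.DataFrame:
    """Keep terms with annotation frequency strictly below ``cutoff``.

    Terms lacking a frequency are kept (the filter cannot judge them) with
    the ``specific`` flag unset and a logged warning.
    """
    if not (0 < cutoff <= 1):
        raise ValueError("cutoff must be in (0, 1]")
    out = table.copy()
    has_freq = out["frequency"].notna()
    n_missing = int((~has_freq).sum())
    if n_missing:
        logger.warning("%d terms lack a frequency value; kept unfiltered", n_missing)
    out["specific"] = has_freq & (out["frequency"] < cutoff)
    keep = ~has_freq | (out["frequency"] < cutoff)
    return out.loc[keep].reset_index(drop=True)
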