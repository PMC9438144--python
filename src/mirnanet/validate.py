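"""Direction-consistency validation of predicted targets against mRNA data.

A predicted target is "validated" when its measured mRNA log2 fold change
has the opposite sign to its node strength: positive strength (many
upregulated miRNAs pointing at the gene) predicts the mRNA goes down, and
vice versa.  Genes with zero strength or exactly zero log2FC carry no
direction and are never flagged consistent.
"""

from __future__ import annotations

import numpy as np
import pandas as pd


def intersect_targets(predictions: pd.DataFrame, mrna_de: pd.DataFrame) -> pd.DataFrame:
    """Inner join of the prediction table with the measured mRNA DE table.

    Gene symbols are compared after whitespace trimming; no alias resolution
    is attempted.  Returns the joined table with universe sizes attached as
    frame attrs (``n_predicted``, ``n_mrna_de``, ``n_overlap``).
    """
    if len(mrna_de) == 0:
        raise ValueError("empty mRNA DE table")
    pred = predictions.copy()
    pred["gene"] = pred["gene"].astype(str).str.strip()
    mrna = mrna_de.copy()
    mrna["gene"] = mrna["gene"].astype(str).str.strip()
    joined = pred.merge(mrna[["gene", "log2fc"]].rename(columns={"log2fc": "mrna_log2fc"}), on="gene", how="inner")
    joined.attrs["n_predicted"] = len(pred)
    joined.attrs["n_mrna_de"] = len(mrna)
    joined.attrs["n_overlap"] = len(joined)
    return joined


def consistency_flags(node_strength, mrna_log2fc) -> np.ndarray:
    """Vectorized consistency rule: opposite, nonzero signs on both sides."""
    s = np.asarray(node_strength, dtype=float)
    f = np.asarray(mrna_log2fc, dtype=float)
    return (s != 0) & (f != 0) & (np.sign(f) == -np.sign(s))


def direction_consistency(joined: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Flag each joined gene as consistent or not; return table + summary.

    The summary carries ``n_overlap`` and ``n_consistent``.
    """
    if len(joined) == 0:
        raise ValueError("empty joined table")
    table = joined.copy()
    table["consistent"] = consistency_flags(table["node_strength"], table["mrna_log2fc"])
    summary = {
        "n_overlap": int(len(table)),
        "n_consistent": int(table["consistent"].sum()),
    }
    if "n_predicted" in joined.attrs:
        summary["n_predicted"] = joined.attrs["n_predicted"]
        summary["n_mrna_de"] = joined.attrs["n_mrna_de"]
    return table, summary


def validate_predictions(predictions: pd.DataFrame, mrna_de: pd.DataFrame) -> tuple[pd.DataFrame, dict]:
    """Join predictions to the mRNA DE table and apply the consistency rule."""
    return direction_consistency(intersect_targets(predictions, mrna_de))


def consistency_report(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Per-contrast summary of the validation outcome.

    ``tables`` maps contrast name to a validated table (with ``consistent``,
    ``node_strength`` and ``mrna_log2fc`` columns).  Consistent genes are
    listed ordered by |node strength| then |mRNA log2FC|, both descending.
    """
    if not tables:
        raise ValueError("no contrasts supplied")
    rows = []
    for contrast, table in tables.items():
        consistent = table[table["consistent"]].copy()
        consistent = consistent.sort_values(
            by=["node_strength", "mrna_log2fc"],
            key=lambda s: s.abs(),
            ascending=False,
            kind="stable",
        )
        rows.append(
            {
                "contrast": contrast,
                "n_overlap": int(len(table)),
                "n_consistent": int(table["consistent"].sum()),
                "consistent_genes": ",".join(consistent["gene"]),
            }
        )
    return pd.DataFrame(rows)
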