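"""Signed bipartite miRNA -> target network and node-strength scoring.

Edges connect differentially expressed miRNAs to their database targets and
carry weight +1 when the miRNA is upregulated, -1 when downregulated.  A
gene's node strength is the sum of its incident edge weights; because a
miRNA represses its targets, positive strength predicts target
downregulation and negative strength predicts upregulation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .io import normalize_mirna_id

logger = logging.getLogger(__name__)


@dataclass
class TargetNetwork:
    """Signed bipartite edges plus the per-miRNA direction that signed them."""

    edges: set[tuple[str, str, int]] = field(default_factory=set)
    mirna_direction: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        pairs = {(m, g) for m, g, _ in self.edges}
        if len(pairs) != len(self.edges):
            raise ValueError("conflicting weights for the same (miRNA, gene) pair")
        for m, _, w in self.edges:
            if m not in self.mirna_direction:
                raise ValueError(f"edge miRNA {m} has no direction")
            expected = 1 if self.mirna_direction[m] == "up" else -1
            if w != expected:
                raise ValueError(f"edge weight for {m} inconsistent with its direction")

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def genes(self) -> set[str]:
        return {g for _, g, _ in self.edges}

    def mirnas(self) -> set[str]:
        return {m for m, _, _ in self.edges}


def build_signed_network(
    pairs: Iterable[tuple[str, str]],
    de_mirnas: pd.DataFrame | Mapping[str, str],
) -> TargetNetwork:
    """Restrict interaction pairs to DE miRNAs and sign them by direction.

    ``de_mirnas`` is either a filtered DE table (feature_id + direction
    columns) or a mapping miRNA id -> 'up'/'down'.  Pairs whose miRNA is not
    DE are dropped (with a logged count); a DE miRNA lacking a direction is
    an error.
    """
    if isinstance(de_mirnas, pd.DataFrame):
        if "direction" not in de_mirnas.columns:
            raise ValueError("DE table lacks a direction column")
        direction = {
            normalize_mirna_id(m): d
            for m, d in zip(de_mirnas["feature_id"], de_mirnas["direction"])
        }
    else:
        direction = {normalize_mirna_id(m): d for m, d in de_mirnas.items()}
    if not direction:
        raise ValueError("no DE miRNAs supplied")
    bad = {m for m, d in direction.items() if d not in ("up", "down")}
    if bad:
        raise ValueError(f"DE miRNAs without a valid direction: {sorted(bad)}")

    edges: set[tuple[str, str, int]] = set()
    dropped = 0
    for mirna, gene in pairs:
        m = normalize_mirna_id(mirna)
        if m not in direction:
            dropped += 1
            continue
        weight = 1 if direction[m] == "up" else -1
        edges.add((m, gene.strip(), weight))
    if dropped:
        logger.info("dropped %d interaction pairs whose miRNA is not DE", dropped)
    used = {m for m, _, _ in edges}
    return TargetNetwork(edges=edges, mirna_direction={m: direction[m] for m in used})


def node_strength(network: TargetNetwork) -> pd.DataFrame:
    """Per-gene node strength table.

    Columns: gene, degree, n_up_edges, n_down_edges, node_strength,
    predicted_direction ('down' for positive strength, 'up' for negative,
    'none' at zero) and the figure emphasis flag (|strength| > 1).
    """
    if not network.edges:
        raise ValueError("empty network")
    rows: dict[str, list[int]] = {}
    for _, gene, weight in network.edges:
        up, down = rows.setdefault(gene, [0, 0])
        if weight > 0:
            rows[gene][0] = up + 1
        else:
            rows[gene][1] = down + 1
    records = []
    for gene in sorted(rows):
        up, down = rows[gene]
        strength = up - down
        direction = "down" if strength > 0 else ("up" if strength < 0 else "none")
        records.append(
            {
                "gene": gene,
                "degree": up + down,
                "n_up_edges": up,
                "n_down_edges": down,
                "node_strength": strength,
                "predicted_direction": direction,
                "emphasized": abs(strength) > 1,
            }
        )
    return pd.DataFrame(records)


def flip_directions(network: TargetNetwork) -> TargetNetwork:
    """Invert every miRNA direction (and hence every edge weight).

    Metamorphic helper: node strengths of the flipped network are the exact
    negation of the original, and applying it twice is the identity.
    """
    return TargetNetwork(
        edges={(m, g, -w) for m, g, w in network.edges},
        mirna_direction={m: ("down" if d == "up" else "up") for m, d in network.mirna_direction.items()},
    )


def top_targets(
    predictions: pd.DataFrame,
    k: int | None = None,
    min_abs_strength: int | None = None,
) -> pd.DataFrame:
    """Targets ranked by |node strength| descending, ties alphabetical.

    ``min_abs_strength=2`` reproduces the figure de-emphasis rule that hides
    genes with |strength| <= 1.
    """
    if len(predictions) == 0:
        raise ValueError("empty prediction table")
    ranked = predictions.copy()
    ranked["_abs"] = ranked["node_strength"].abs()
    ranked = ranked.sort_values(["_abs", "gene"], ascending=[False, True], kind="stable").drop(columns="_abs")
    if min_abs_strength is not None:
        ranked = ranked[ranked["node_strength"].abs() >= min_abs_strength]
    if k is not None:
        ranked = ranked.head(k)
    return ranked.reset_index(drop=True)
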