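"""Readers and writers for every external file the pipeline touches.

All tabular formats are plain text: counts TSV, design CSV, interaction TSV,
GMT gene sets, mRNA DE TSV.  Readers validate strictly and raise
:class:`ParseError` with the offending line number; every writer/reader pair
round-trips losslessly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

VALID_GROUPS = ("healthy", "interictal", "ictal")
INTERACTION_SOURCES = ("validated", "predicted_score", "predicted_mirsvr")

#: default database score thresholds; both inequalities are strict
SCORE_MIN = 80.0
MIRSVR_MAX = -1.2


class ParseError(ValueError):
    """Malformed input file; message carries the line number."""


def parse_decimal_comma(text: str) -> float:
    """Parse a number that may use a decimal comma (``"2,59"`` -> 2.59).

    Transcriptions of European journal tables print comma decimals; this
    helper accepts either convention.
    """
    return float(text.strip().replace(",", "."))


# ---------------------------------------------------------------------------
# counts + design
# ---------------------------------------------------------------------------

@dataclass
class CountMatrix:
    """miRNA-by-sample non-negative integer counts."""

    feature_ids: list[str]
    sample_ids: list[str]
    counts: np.ndarray  # (n_features, n_samples) int64

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise ValueError("counts shape does not match id lists")
        if len(set(self.feature_ids)) != len(self.feature_ids):
            raise ValueError("duplicate feature ids")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise ValueError("duplicate sample ids")
        if len(self.sample_ids) < 2:
            raise ValueError("need at least 2 samples")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)) or np.any(self.counts % 1 != 0):
                raise ValueError("counts must be finite integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=0).astype(float)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)


def read_counts(path: str | Path) -> CountMatrix:
    """Read a tab-separated count matrix (first column feature id)."""
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise ParseError(f"{path}:1: empty header")
        sample_ids = header.split("\t")[1:]
        feature_ids: list[str] = []
        rows: list[list[int]] = []
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != len(sample_ids) + 1:
                raise ParseError(f"{path}:{lineno}: expected {len(sample_ids) + 1} fields, got {len(parts)}")
            feature_ids.append(parts[0].strip())
            try:
                vals = [int(p) for p in parts[1:]]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer count: {exc}") from None
            if any(v < 0 for v in vals):
                raise ParseError(f"{path}:{lineno}: negative count")
            rows.append(vals)
    if len(set(feature_ids)) != len(feature_ids):
        raise ParseError(f"{path}: duplicate feature ids")
    return CountMatrix(feature_ids, sample_ids, np.asarray(rows, dtype=np.int64))


def write_counts(cm: CountMatrix, path: str | Path) -> None:
    cm.to_frame().to_csv(path, sep="\t", index_label="feature_id")


@dataclass
class StudyDesign:
    """Sample annotation: group membership and self-pairing by patient.

    Ictal samples must share a patient id with an interictal sample so the
    within-patient paired contrast is well defined.
    """

    table: pd.DataFrame  # columns: sample_id, group, patient_id (may be NA)

    def __post_init__(self) -> None:
        required = {"sample_id", "group"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"design table needs columns {sorted(required)}")
        if "patient_id" not in self.table.columns:
            self.table = self.table.assign(patient_id=pd.NA)
        if self.table["sample_id"].duplicated().any():
            raise ValueError("duplicate sample ids in design")
        bad = set(self.table["group"]) - set(VALID_GROUPS)
        if bad:
            raise ValueError(f"unknown groups: {sorted(bad)}")
        inter_pat = set(self.table.loc[self.table.group == "interictal", "patient_id"].dropna())
        ictal = self.table[self.table.group == "ictal"]
        if len(ictal) and not set(ictal["patient_id"].dropna()) <= inter_pat:
            raise ValueError("every ictal sample needs a patient_id shared with an interictal sample")
        if len(ictal) and ictal["patient_id"].isna().any():
            raise ValueError("ictal samples must carry a patient_id")

    def samples_in(self, group: str) -> list[str]:
        return list(self.table.loc[self.table.group == group, "sample_id"])

    def paired_samples(self) -> list[tuple[str, str, str]]:
        """(patient_id, ictal_sample, interictal_sample) triples."""
        ictal = self.table[self.table.group == "ictal"].set_index("patient_id")["sample_id"]
        inter = self.table[self.table.group == "interictal"].set_index("patient_id")["sample_id"]
        return [(str(p), ictal[p], inter[p]) for p in ictal.index if p in inter.index]


def read_design(path: str | Path) -> StudyDesign:
    df = pd.read_csv(path, dtype=str)
    return StudyDesign(df)


def write_design(design: StudyDesign, path: str | Path) -> None:
    design.table.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# interaction database
# ---------------------------------------------------------------------------

def normalize_mirna_id(mirna: str) -> str:
    """Trim whitespace and lower-case the species/miR prefix.

    Gene symbol case is preserved elsewhere; miRNA ids in the wild mix
    ``hsa-miR-…``/``HSA-MIR-…`` styles, so matching is case-insensitive on
    the prefix while keeping the conventional rendering.
    """
    m = mirna.strip()
    if m.lower().startswith("hsa-"):
        # canonicalise "hsa-" and "mir"/"let" casing, keep the suffix as-is
        parts = m.split("-")
        parts[0] = "hsa"
        if len(parts) > 1:
            stem = parts[1]
            if stem.lower() == "mir":
                parts[1] = "miR"
            elif stem.lower() == "let":
                parts[1] = "let"
        m = "-".join(parts)
    return m


def read_interaction_records(path: str | Path) -> pd.DataFrame:
    """Read raw interaction records (mirna_id, gene_symbol, source, score)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"mirna_id": str, "gene_symbol": str, "source": str})
    required = {"mirna_id", "gene_symbol", "source"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    bad = df.loc[~df["source"].isin(INTERACTION_SOURCES)]
    if len(bad):
        lineno = bad.index[0] + 2  # header + 1-based
        raise ParseError(f"{path}:{lineno}: unknown source tier {bad['source'].iloc[0]!r}")
    if "score" not in df.columns:
        df["score"] = np.nan
    predicted = df["source"] != "validated"
    if df.loc[predicted, "score"].isna().any():
        lineno = df.loc[predicted & df["score"].isna()].index[0] + 2
        raise ParseError(f"{path}:{lineno}: predicted-tier record lacks a score")
    if (df["mirna_id"].str.strip() == "").any() or (df["gene_symbol"].str.strip() == "").any():
        raise ParseError(f"{path}: empty identifier")
    return df


def filter_interactions(
    records: pd.DataFrame,
    score_min: float = SCORE_MIN,
    mirsvr_max: float = MIRSVR_MAX,
) -> set[tuple[str, str]]:
    """Apply per-tier thresholds and return unique (miRNA, gene) pairs.

    The validated tier passes unfiltered; the score tier requires a score
    strictly above ``score_min``; the mirSVR tier a score strictly below
    ``mirsvr_max``.  Duplicate pairs across tiers collapse to one edge.
    """
    keep = np.zeros(len(records), dtype=bool)
    src = records["source"].to_numpy()
    score = records["score"].to_numpy(dtype=float)
    keep |= src == "validated"
    keep |= (src == "predicted_score") & (score > score_min)
    keep |= (src == "predicted_mirsvr") & (score < mirsvr_max)
    pairs = {
        (normalize_mirna_id(m), g.strip())
        for m, g in zip(records.loc[keep, "mirna_id"], records.loc[keep, "gene_symbol"])
    }
    return pairs


def read_interactions(
    path: str | Path,
    score_min: float = SCORE_MIN,
    mirsvr_max: float = MIRSVR_MAX,
) -> set[tuple[str, str]]:
    """Read an interaction TSV and return the threshold-filtered unique pairs."""
    return filter_interactions(read_interaction_records(path), score_min, mirsvr_max)


def write_interaction_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# gene sets (GMT)
# ---------------------------------------------------------------------------

@dataclass
class GeneSet:
    term_id: str
    term_name: str
    members: list[str]
    frequency: float | None = None  # proportion of gene products annotated

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.term_id} has no members")
        if self.frequency is not None and not (0.0 < self.frequency <= 1.0):
            raise ValueError(f"gene set {self.term_id}: frequency must be in (0, 1]")


@dataclass
class GeneSetCollection:
    sets: list[GeneSet] = field(default_factory=list)

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, term_id: str) -> GeneSet:
        for gs in self.sets:
            if gs.term_id == term_id:
                return gs
        raise KeyError(term_id)


def read_gene_sets(path: str | Path) -> GeneSetCollection:
    """Read a GMT file: term_id TAB description TAB member....

    A per-term annotation frequency may be encoded in the description field
    as ``freq=<x>``.
    """
    path = Path(path)
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ParseError(f"{path}:{lineno}: gene set has an empty member list")
            term_id, desc = parts[0], parts[1]
            freq = None
            name = desc
            for token in desc.split(";"):
                token = token.strip()
                if token.startswith("freq="):
                    freq = float(token[len("freq="):])
                    name = ";".join(t for t in desc.split(";") if not t.strip().startswith("freq=")).strip()
            members = [g.strip() for g in parts[2:] if g.strip()]
            if not members:
                raise ParseError(f"{path}:{lineno}: gene set has an empty member list")
            try:
                sets.append(GeneSet(term_id, name, members, freq))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from None
    return GeneSetCollection(sets)


def write_gene_sets(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gs in collection:
            desc = gs.term_name
            if gs.frequency is not None:
                desc = f"{desc};freq={gs.frequency}" if desc else f"freq={gs.frequency}"
            fh.write("\t".join([gs.term_id, desc, *gs.members]) + "\n")


# ---------------------------------------------------------------------------
# mRNA DE table + generic tables
# ---------------------------------------------------------------------------

def read_mrna_de(path: str | Path) -> pd.DataFrame:
    """Read an mRNA DE table: gene TAB log2fc TAB p."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc"}
    if not required.issubset(df.columns):
        raise ParseError(f"{path}: need columns {sorted(required)}")
    if "p" not in df.columns:
        df["p"] = np.nan
    df["gene"] = df["gene"].astype(str).str.strip()
    return df


def write_mrna_de(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Write any result table as TSV (lossless for string/float columns)."""
    df.to_csv(path, sep="\t", index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


# ---------------------------------------------------------------------------
# network export
# ---------------------------------------------------------------------------

def write_network(network, predictions: pd.DataFrame, path_prefix: str | Path) -> dict[str, Path]:
    """Export a signed target network as SIF + GraphML + node-attribute TSV.

    SIF relation names encode the edge sign (``up_mirna_edge`` for +1 edges
    from upregulated miRNAs, ``down_mirna_edge`` for -1).  The attribute TSV
    carries node strength, predicted direction and the emphasis flag used in
    network figures (genes with |strength| <= 1 are de-emphasized).
    """
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    sif_path = prefix.with_suffix(".sif")
    graphml_path = prefix.with_suffix(".graphml")
    attr_path = Path(str(prefix) + "_nodes.tsv")

    with open(sif_path, "w") as fh:
        for mirna, gene, weight in sorted(network.edges):
            rel = "up_mirna_edge" if weight > 0 else "down_mirna_edge"
            fh.write(f"{mirna}\t{rel}\t{gene}\n")

    g = nx.DiGraph()
    strengths = dict(zip(predictions["gene"], predictions["node_strength"]))
    for mirna, gene, weight in network.edges:
        g.add_node(mirna, kind="mirna", direction=network.mirna_direction[mirna])
        g.add_node(gene, kind="gene", node_strength=int(strengths.get(gene, 0)))
        g.add_edge(mirna, gene, weight=int(weight))
    nx.write_graphml(g, graphml_path)

    write_table(predictions, attr_path)
    return {"sif": sif_path, "graphml": graphml_path, "nodes": attr_path}
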