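"""End-to-end orchestration: counts -> DE -> network -> validation -> ORA.

Each contrast runs the full chain and writes six artifacts (DE table, DE
subset, node-strength table, validation table, up- and down-target
enrichment tables) plus SIF/GraphML network exports; a JSON manifest records
thresholds, seed and per-stage row counts so a run is self-describing and
reruns can be compared file-for-file.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .de import (
    CONTRASTS,
    FC_THRESHOLD,
    P_THRESHOLD,
    average_rank,
    count_directions,
    filter_de,
    fit_moderated_de,
)
from .enrichment import FREQ_CUTOFF, ORA_ALPHA, run_ora, specificity_filter
from .io import (
    MIRSVR_MAX,
    SCORE_MIN,
    CountMatrix,
    StudyDesign,
    read_counts,
    read_design,
    read_gene_sets,
    read_interactions,
    read_mrna_de,
    read_table,
    write_network,
    write_table,
)
from .network import build_signed_network, node_strength
from .normalize import normalize
from .validate import validate_predictions

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Inputs, outputs and every tunable threshold of a pipeline run."""

    counts_path: str | Path = "counts.tsv"
    design_path: str | Path = "design.csv"
    interactions_path: str | Path = "interactions.tsv"
    mrna_de_path: str | Path = "mrna_de.tsv"
    gene_sets_path: str | Path = "gene_sets.gmt"
    out_dir: str | Path = "results"
    contrasts: tuple[str, ...] = CONTRASTS
    de_table_path: str | Path | None = None  # inject a precomputed DE table, skip the DE stage
    fc_thresh: float = FC_THRESHOLD
    p_thresh: float = P_THRESHOLD
    score_min: float = SCORE_MIN
    mirsvr_max: float = MIRSVR_MAX
    freq_cutoff: float = FREQ_CUTOFF
    ora_alpha: float = ORA_ALPHA
    rank_scope: str = "all_tested"
    seed: int = 0

    def thresholds(self) -> dict:
        return {
            "fc_thresh": self.fc_thresh,
            "p_thresh": self.p_thresh,
            "score_min": self.score_min,
            "mirsvr_max": self.mirsvr_max,
            "freq_cutoff": self.freq_cutoff,
            "ora_alpha": self.ora_alpha,
        }


def _design_matrix(design: StudyDesign):
    import numpy as np

    groups = sorted(design.table["group"].unique())
    x = np.zeros((len(design.table), len(groups)))
    for j, g in enumerate(groups):
        x[(design.table["group"] == g).to_numpy(), j] = 1.0
    return x


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every contrast through DE, network, validation and enrichment.

    Returns the manifest dictionary (also written to ``manifest.json`` in
    the output directory).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "thresholds": config.thresholds(),
        "contrasts": {},
    }

    pairs = read_interactions(config.interactions_path, config.score_min, config.mirsvr_max)
    universe = sorted({g for _, g in pairs})
    mrna_de = read_mrna_de(config.mrna_de_path)
    collection = read_gene_sets(config.gene_sets_path)
    logger.info("interaction pairs after filtering: %d (universe %d genes)", len(pairs), len(universe))

    injected_de = read_table(config.de_table_path) if config.de_table_path else None
    expr = design = None
    if injected_de is None:
        counts = read_counts(config.counts_path)
        design = read_design(config.design_path)
        expr = normalize(counts, _design_matrix(design))

    for contrast in config.contrasts:
        cdir = out / contrast
        cdir.mkdir(parents=True, exist_ok=True)
        stage: dict = {}

        if injected_de is not None:
            de_table = injected_de.copy()
            if "direction" not in de_table.columns:
                from .de import classify_direction

                de_table["direction"] = classify_direction(de_table["fc_signed"].to_numpy())
            if "avg_rank" not in de_table.columns:
                from .de import rank_by_fc_and_p

                de_table["avg_rank"] = rank_by_fc_and_p(de_table)
        else:
            de_table = fit_moderated_de(expr, design, contrast, rank_scope=config.rank_scope)
        write_table(de_table, cdir / "de_full.tsv")

        de_subset = average_rank(de_table, scope=config.rank_scope, fc_thresh=config.fc_thresh, p_thresh=config.p_thresh)
        n_up, n_down = count_directions(de_subset)
        stage["de"] = {"tested": len(de_table), "de": len(de_subset), "up": n_up, "down": n_down}
        write_table(de_subset, cdir / "de_filtered.tsv")
        logger.info("%s: %d DE miRNAs (%d up / %d down)", contrast, len(de_subset), n_up, n_down)

        if len(de_subset) == 0:
            stage["skipped"] = "no DE miRNAs; downstream stages skipped"
            manifest["contrasts"][contrast] = stage
            continue

        net = build_signed_network(pairs, de_subset)
        if not net.edges:
            stage["skipped"] = "no network edges; downstream stages skipped"
            manifest["contrasts"][contrast] = stage
            continue
        predictions = node_strength(net)
        stage["network"] = {
            "edges": net.n_edges,
            "genes": len(predictions),
            "predicted_down": int((predictions["predicted_direction"] == "down").sum()),
            "predicted_up": int((predictions["predicted_direction"] == "up").sum()),
        }
        write_table(predictions, cdir / "node_strength.tsv")
        write_network(net, predictions, cdir / "network")

        validated, summary = validate_predictions(predictions, mrna_de)
        stage["validation"] = summary
        write_table(
            validated[["gene", "node_strength", "predicted_direction", "mrna_log2fc", "consistent"]],
            cdir / "validation.tsv",
        )

        stage["enrichment"] = {}
        for direction in ("down", "up"):
            query = set(predictions.loc[predictions["predicted_direction"] == direction, "gene"])
            if not query:
                stage["enrichment"][direction] = {"skipped": "no predicted targets"}
                continue
            ora = run_ora(query, universe, collection, alpha=config.ora_alpha)
            ora_specific = specificity_filter(ora, cutoff=config.freq_cutoff)
            write_table(ora, cdir / f"enrichment_{direction}.tsv")
            write_table(ora_specific, cdir / f"enrichment_{direction}_specific.tsv")
            stage["enrichment"][direction] = {
                "terms_tested": len(ora),
                "significant": int(ora["significant"].sum()),
                "specific": len(ora_specific),
            }

        manifest["contrasts"][contrast] = stage

    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def summarize_run(manifest_path: str | Path) -> str:
    """Human-readable per-stage report from a run manifest."""
    path = Path(manifest_path)
    if not path.exists():
        raise FileNotFoundError(f"no manifest at {path}")
    manifest = json.loads(path.read_text())
    lines = [f"pipeline run (version {manifest.get('version', '?')}, seed {manifest.get('seed')})"]
    for key, val in sorted(manifest.get("thresholds", {}).items()):
        lines.append(f"  threshold {key} = {val}")
    for contrast, stage in manifest.get("contrasts", {}).items():
        lines.append(f"contrast {contrast}:")
        de = stage.get("de", {})
        lines.append(
            f"  DE: {de.get('de', 0)} of {de.get('tested', 0)} miRNAs "
            f"({de.get('up', 0)} up / {de.get('down', 0)} down)"
        )
        if "skipped" in stage:
            lines.append(f"  downstream: SKIPPED ({stage['skipped']})")
            continue
        net = stage.get("network", {})
        lines.append(
            f"  network: {net.get('edges', 0)} edges, {net.get('genes', 0)} genes "
            f"({net.get('predicted_down', 0)} predicted down / {net.get('predicted_up', 0)} up)"
        )
        val = stage.get("validation", {})
        lines.append(f"  validation: {val.get('n_consistent', 0)} of {val.get('n_overlap', 0)} overlapping genes consistent")
        for direction, enr in stage.get("enrichment", {}).items():
            if "skipped" in enr:
                lines.append(f"  enrichment ({direction}): skipped")
            else:
                lines.append(
                    f"  enrichment ({direction}): {enr['significant']} of {enr['terms_tested']} terms significant, "
                    f"{enr['specific']} after specificity filter"
                )
    return "\n".join(lines)
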