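"""Synthetic inputs with the statistical structure the pipeline assumes.

The generator emulates a three-group PBMC small RNA-seq study: healthy
controls, migraine patients sampled between attacks (interictal) and during
an attack (ictal), where ictal samples are self-paired to the interictal
sample of the same patient.  Counts are negative-binomial with log-linear
group effects, a shared patient-level random effect on the log-mean for
paired samples and per-sample log-normal biological noise.  Alongside the
counts it fabricates a three-tier miRNA-target interaction database whose
scores straddle the filtering thresholds, an mRNA DE table whose fold-change
signs oppose the planted node strengths (up to a configurable flip
fraction), and a toy gene-set annotation with one planted enriched term.

All randomness flows from the single integer seed in the configuration via
a splittable seed sequence, so each stage is independently reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    CountMatrix,
    GeneSet,
    GeneSetCollection,
    StudyDesign,
    write_counts,
    write_design,
    write_gene_sets,
    write_interaction_records,
    write_mrna_de,
)

DEFAULT_GROUPS = {"healthy": 12, "interictal": 16, "ictal": 8}


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    The defaults mirror the emulated cohort: 12 healthy controls, 16
    interictal samples and 8 ictal samples self-paired to the first 8
    interictal patients.  Planted effects are log2 shifts applied to the
    groups in ``effect_groups`` relative to the remaining groups.
    """

    n_mirna: int = 300
    n_gene: int = 600
    n_per_group: dict[str, int] = field(default_factory=lambda: dict(DEFAULT_GROUPS))
    planted_de: dict[str, float] = field(default_factory=dict)  # feature id -> signed log2 effect
    effect_groups: tuple[str, ...] = ("interictal", "ictal")
    dispersion: float = 0.1
    lib_size_range: tuple[int, int] = (800_000, 1_200_000)
    pairing_correlation: float = 0.5
    sample_noise_sd: float = 0.25  # log2-scale biological noise per sample
    targets_per_mirna: tuple[int, int] = (10, 40)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_mirna <= 0 or self.n_gene <= 0:
            raise ValueError("dimensions must be positive")
        if any(n <= 0 for n in self.n_per_group.values()):
            raise ValueError("group sizes must be positive")
        if self.dispersion <= 0:
            raise ValueError("dispersion must be positive")
        if not (0 <= self.pairing_correlation < 1):
            raise ValueError("pairing_correlation must lie in [0, 1)")
        if self.lib_size_range[0] < 1 or self.lib_size_range[1] < self.lib_size_range[0]:
            raise ValueError("invalid library size range")
        if any(not np.isfinite(v) for v in self.planted_de.values()):
            raise ValueError("planted effects must be finite")

    def seeds(self) -> dict[str, np.random.SeedSequence]:
        """Stage-wise child seeds from the single configuration seed."""
        children = np.random.SeedSequence(self.seed).spawn(4)
        return dict(zip(("counts", "interactions", "mrna", "gene_sets"), children))


@dataclass
class GroundTruth:
    """What the generator planted, for parameter-recovery tests."""

    true_de_mirnas: dict[str, float] = field(default_factory=dict)
    true_edges: set[tuple[str, str]] = field(default_factory=set)
    true_node_strengths: dict[str, int] = field(default_factory=dict)
    true_enriched_terms: set[str] = field(default_factory=set)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "true_de_mirnas": self.true_de_mirnas,
            "true_edges": sorted(list(e) for e in self.true_edges),
            "true_node_strengths": self.true_node_strengths,
            "true_enriched_terms": sorted(self.true_enriched_terms),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def mirna_ids(n: int) -> list[str]:
    return [f"hsa-miR-sim{i:04d}" for i in range(1, n + 1)]


def gene_ids(n: int) -> list[str]:
    return [f"GENE{i:04d}" for i in range(1, n + 1)]


def default_planted_effects(n_mirna: int, n_de: int = 30, rng_seed: int = 0) -> dict[str, float]:
    """A realistic planted-effect map: alternating-sign log2 shifts with
    magnitudes spanning the 1.4- to 3.5-fold range typical of PBMC miRNA
    contrasts."""
    rng = np.random.default_rng(rng_seed)
    ids = mirna_ids(n_mirna)
    chosen = rng.choice(n_mirna, size=min(n_de, n_mirna), replace=False)
    effects = {}
    for j, idx in enumerate(sorted(chosen)):
        magnitude = rng.uniform(0.6, 1.8)
        effects[ids[idx]] = magnitude if j % 2 == 0 else -magnitude
    return effects


def _build_design(config: SimulationConfig) -> StudyDesign:
    rows = []
    n_inter = config.n_per_group.get("interictal", 0)
    n_ictal = config.n_per_group.get("ictal", 0)
    if n_ictal > n_inter:
        raise ValueError("every ictal sample needs an interictal patient to pair with")
    for group, n in config.n_per_group.items():
        for i in range(1, n + 1):
            patient = pd.NA
            if group == "interictal":
                patient = f"P{i:02d}"
            elif group == "ictal":
                patient = f"P{i:02d}"  # paired with the i-th interictal patient
            rows.append({"sample_id": f"{group}_{i:02d}", "group": group, "patient_id": patient})
    return StudyDesign(pd.DataFrame(rows))


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, StudyDesign, GroundTruth]:
    """Negative-binomial counts with planted group effects and self-pairing.

    Counts are gamma-Poisson draws around per-sample expected values
    ``mu = base_abundance * lib_size/1e6 * 2**(effect + patient + noise)``:
    planted features shift the log2 mean of the effect groups, patients with
    both an ictal and an interictal sample share a Gaussian log2 random
    effect whose variance is set by ``pairing_correlation`` relative to the
    per-sample noise, and the gamma stage adds the NB dispersion.
    """
    seeds = config.seeds()
    rng = np.random.default_rng(seeds["counts"])
    design = _build_design(config)
    samples = list(design.table["sample_id"])
    groups = dict(zip(design.table["sample_id"], design.table["group"]))
    patients = dict(zip(design.table["sample_id"], design.table["patient_id"]))

    features = mirna_ids(config.n_mirna)
    unknown = set(config.planted_de) - set(features)
    if unknown:
        raise ValueError(f"planted ids not in the simulated feature set: {sorted(unknown)}")

    g, n = config.n_mirna, len(samples)
    base = rng.lognormal(mean=np.log(80.0), sigma=1.6, size=g)
    base *= 1e6 / base.sum()  # counts-per-million scale: expected depth = library size
    lib_sizes = rng.integers(config.lib_size_range[0], config.lib_size_range[1] + 1, size=n)

    effect = np.zeros((g, n))
    fid_index = {f: i for i, f in enumerate(features)}
    for fid, log2fc in config.planted_de.items():
        for j, s in enumerate(samples):
            if groups[s] in config.effect_groups:
                effect[fid_index[fid], j] = log2fc

    # patient random effect for self-paired samples
    rho = config.pairing_correlation
    sd_noise = config.sample_noise_sd
    sd_patient = sd_noise * np.sqrt(rho / (1.0 - rho)) if rho > 0 else 0.0
    patient_counts = pd.Series([p for p in patients.values() if pd.notna(p)]).value_counts()
    paired_patients = sorted(patient_counts[patient_counts >= 2].index)
    b = rng.normal(0.0, sd_patient, size=(g, len(paired_patients))) if paired_patients else np.zeros((g, 0))
    p_index = {p: i for i, p in enumerate(paired_patients)}
    noise = rng.normal(0.0, sd_noise, size=(g, n))

    log2_mu = np.log2(base)[:, None] + effect + noise
    for j, s in enumerate(samples):
        p = patients[s]
        if pd.notna(p) and p in p_index:
            log2_mu[:, j] += b[:, p_index[p]]

    mu = 2.0**log2_mu * (lib_sizes / 1e6)[None, :]
    shape = 1.0 / config.dispersion
    lam = rng.gamma(shape, mu * config.dispersion)
    counts = rng.poisson(lam).astype(np.int64)
    cm = CountMatrix(features, samples, counts)

    truth = GroundTruth(true_de_mirnas=dict(config.planted_de))
    _plant_edges(config, truth, rng=np.random.default_rng(seeds["interactions"]))
    return cm, design, truth


def _plant_edges(config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator) -> None:
    """Attach a true target set to every planted DE miRNA and derive the
    ground-truth node strengths."""
    genes = gene_ids(config.n_gene)
    lo, hi = config.targets_per_mirna
    strengths: dict[str, int] = {}
    for mirna in sorted(truth.true_de_mirnas):
        k = int(rng.integers(lo, hi + 1))
        targets = rng.choice(config.n_gene, size=min(k, config.n_gene), replace=False)
        sign = 1 if truth.true_de_mirnas[mirna] > 0 else -1
        for t in targets:
            gene = genes[t]
            truth.true_edges.add((mirna, gene))
            strengths[gene] = strengths.get(gene, 0) + sign
    truth.true_node_strengths = strengths


def simulate_interaction_db(
    config: SimulationConfig,
    truth: GroundTruth,
    n_decoys: int | None = None,
) -> pd.DataFrame:
    """Interaction records in three source tiers with threshold-straddling scores.

    Every true edge is emitted in one tier with a passing score (validated
    records carry no score); decoy records — pairs outside the true edge set
    — are emitted in the two predicted tiers with failing scores, so that
    threshold filtering recovers exactly the true edges.
    """
    if not truth.true_edges:
        raise ValueError("ground truth has no edges")
    rng = np.random.default_rng(config.seeds()["interactions"].spawn(1)[0])
    genes = gene_ids(config.n_gene)
    mirnas = mirna_ids(config.n_mirna)
    rows = []
    tiers = ("validated", "predicted_score", "predicted_mirsvr")
    for mirna, gene in sorted(truth.true_edges):
        tier = tiers[rng.integers(0, 3)]
        if tier == "validated":
            score = np.nan
        elif tier == "predicted_score":
            score = rng.uniform(80.1, 100.0)  # strictly above the 80.0 cutoff
        else:
            score = rng.uniform(-3.0, -1.25)  # strictly below the -1.2 cutoff
        rows.append({"mirna_id": mirna, "gene_symbol": gene, "source": tier, "score": score})

    n_decoys = len(truth.true_edges) if n_decoys is None else n_decoys
    made = 0
    attempts = 0
    while made < n_decoys and attempts < 50 * n_decoys:
        attempts += 1
        mirna = mirnas[rng.integers(0, config.n_mirna)]
        gene = genes[rng.integers(0, config.n_gene)]
        if (mirna, gene) in truth.true_edges:
            continue
        if rng.random() < 0.5:
            rows.append({"mirna_id": mirna, "gene_symbol": gene, "source": "predicted_score",
                         "score": rng.uniform(10.0, 79.9)})
        else:
            rows.append({"mirna_id": mirna, "gene_symbol": gene, "source": "predicted_mirsvr",
                         "score": rng.uniform(-1.19, 0.0)})
        made += 1
    return pd.DataFrame(rows)


def simulate_mrna_logfc(
    truth: GroundTruth,
    noise_sd: float = 0.2,
    flip_fraction: float = 0.0,
    seed: int = 0,
    magnitude_mean: float = 1.5,
    magnitude_sd: float = 0.5,
    n_background: int = 50,
) -> pd.DataFrame:
    """mRNA DE table whose fold-change signs oppose the planted strengths.

    For every gene with nonzero true node strength the log2FC sign is the
    opposite of the strength sign, except for a ``flip_fraction`` of genes
    whose sign is inverted.  Magnitudes are |Normal(magnitude_mean,
    magnitude_sd)| plus Gaussian noise, floored so noise never crosses zero.
    Background genes absent from the target universe pad the table.
    """
    if not (0.0 <= flip_fraction <= 1.0):
        raise ValueError("flip_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    rows = []
    for gene in sorted(truth.true_node_strengths):
        strength = truth.true_node_strengths[gene]
        if strength == 0:
            continue
        sign = -np.sign(strength)
        if rng.random() < flip_fraction:
            sign = -sign
        magnitude = abs(rng.normal(magnitude_mean, magnitude_sd)) + rng.normal(0.0, noise_sd)
        magnitude = max(magnitude, 0.05)
        rows.append({"gene": gene, "log2fc": sign * magnitude, "p": rng.uniform(1e-5, 0.049)})
    for i in range(n_background):
        sign = 1 if rng.random() < 0.5 else -1
        rows.append(
            {
                "gene": f"BGGENE{i:04d}",
                "log2fc": sign * (abs(rng.normal(magnitude_mean, magnitude_sd)) + 0.05),
                "p": rng.uniform(1e-5, 0.049),
            }
        )
    return pd.DataFrame(rows)


def simulate_gene_sets(
    n_terms: int,
    truth: GroundTruth,
    seed: int = 0,
    planted_size: int = 20,
    term_size_range: tuple[int, int] = (15, 60),
    n_universe_genes: int | None = None,
) -> GeneSetCollection:
    """Toy annotation with one planted term enriched in high-|strength| genes.

    The planted term is a sample of the genes with the largest positive node
    strengths (the predicted-downregulated targets) and carries a low
    annotation frequency; the remaining terms are random draws from the gene
    universe with frequencies on both sides of the 0.15 specificity cutoff.
    Updates ``truth.true_enriched_terms`` in place.
    """
    if n_terms < 2:
        raise ValueError("need at least 2 terms")
    rng = np.random.default_rng(seed)
    strengths = truth.true_node_strengths
    if not strengths:
        raise ValueError("ground truth has no node strengths")
    universe = sorted({g for g, _ in ((g, s) for g, s in strengths.items())})
    if n_universe_genes:
        universe = universe[:n_universe_genes]

    down_targets = sorted((g for g, s in strengths.items() if s > 0), key=lambda g: (-strengths[g], g))
    planted_members = down_targets[: max(5, min(planted_size, len(down_targets)))]
    planted = GeneSet("TERM0001", "planted enriched process", planted_members, frequency=0.05)
    truth.true_enriched_terms = {planted.term_id}

    sets = [planted]
    for i in range(2, n_terms + 1):
        size = int(rng.integers(term_size_range[0], min(term_size_range[1], len(universe)) + 1))
        members = list(rng.choice(universe, size=size, replace=False))
        # frequencies deliberately straddle the 0.15 specificity cutoff
        freq = float(rng.uniform(0.01, 0.14)) if i % 2 == 0 else float(rng.uniform(0.16, 0.6))
        sets.append(GeneSet(f"TERM{i:04d}", f"random process {i}", members, frequency=freq))
    return GeneSetCollection(sets)


def write_simulated_inputs(
    config: SimulationConfig,
    out_dir: str | Path,
    flip_fraction: float = 0.0,
    n_terms: int = 20,
) -> dict[str, Path]:
    """Generate and write every pipeline input (plus a truth JSON) to disk."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cm, design, truth = simulate_counts(config)
    records = simulate_interaction_db(config, truth)
    seeds = config.seeds()
    mrna = simulate_mrna_logfc(truth, flip_fraction=flip_fraction, seed=seeds["mrna"].generate_state(1)[0] % (2**31))
    collection = simulate_gene_sets(n_terms, truth, seed=seeds["gene_sets"].generate_state(1)[0] % (2**31))

    paths = {
        "counts": out / "counts.tsv",
        "design": out / "design.csv",
        "interactions": out / "interactions.tsv",
        "mrna_de": out / "mrna_de.tsv",
        "gene_sets": out / "gene_sets.gmt",
        "truth": out / "truth.json",
    }
    write_counts(cm, paths["counts"])
    write_design(design, paths["design"])
    write_interaction_records(records, paths["interactions"])
    write_mrna_de(mrna, paths["mrna_de"])
    write_gene_sets(collection, paths["gene_sets"])
    truth.to_json(paths["truth"])
    return paths
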