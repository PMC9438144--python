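"""Bundled reference tables from a published PBMC migraine small RNA-seq cohort.

The cohort compared peripheral blood mononuclear cell miRNA expression in
episodic migraine patients sampled between attacks (interictal), during an
attack (ictal, self-paired to the interictal sample of the same patient) and
in healthy controls.  The published differential-expression lists and the
mRNA-level validation pairs are bundled here so the direction-classification,
average-rank and direction-consistency machinery can be exercised on real
printed values without access to the raw reads.

Fold changes are signed linear fold changes (|FC| >= 1; negative = down),
p-values are raw moderated-test p-values, and ``avg_rank_published`` is the
mean of the fold-change and p-value ranks over the full tested miRNA set as
printed.  The validation tables pair each gene's measured mRNA log2 fold
change with its predicted node strength.
"""

from __future__ import annotations

import pandas as pd

# (miRNA, signed fold change, raw p, published average rank)
_INTERICTAL_VS_HEALTHY_DE = [
    ("hsa-miR-5189-3p", 2.59, 0.0057, 1),
    ("hsa-miR-96-5p", -2.40, 0.0032, 2),
    ("hsa-miR-3613-5p", 2.55, 0.0101, 3),
    ("hsa-miR-99a-3p", 2.37, 0.0079, 4),
    ("hsa-miR-542-3p", 2.40, 0.0164, 5),
    ("hsa-miR-6803-3p", 2.19, 0.0162, 6),
    ("hsa-miR-6731-3p", -2.14, 0.0084, 7),
    ("hsa-miR-577", -2.17, 0.0200, 8),
    ("hsa-miR-95-3p", -2.06, 0.0184, 9),
    ("hsa-miR-556-3p", -2.18, 0.0228, 10),
    ("hsa-miR-412-5p", -2.36, 0.0290, 11),
    ("hsa-miR-5701", -2.24, 0.0263, 12),
    ("hsa-miR-3064-5p", 2.10, 0.0247, 13),
    ("hsa-miR-196a-5p", -2.55, 0.0450, 14),
    ("hsa-miR-5189-5p", 1.93, 0.0222, 15),
    ("hsa-let-7i-3p", -1.82, 0.0067, 16),
    ("hsa-miR-1277-5p", 2.07, 0.0402, 17),
    ("hsa-miR-29b-3p", -1.85, 0.0214, 18),
    ("hsa-miR-4676-3p", 1.87, 0.0261, 19),
    ("hsa-miR-548j-3p", 1.91, 0.0453, 20),
    ("hsa-miR-1260b", 1.78, 0.0361, 24),
    ("hsa-miR-326", 1.62, 0.0027, 26),
    ("hsa-miR-3174", 1.79, 0.0480, 27),
    ("hsa-miR-210-3p", 1.77, 0.0461, 31),
    ("hsa-miR-32-5p", -1.65, 0.0373, 34),
    ("hsa-miR-342-3p", -1.60, 0.0307, 40),
    ("hsa-miR-3607-3p", -1.59, 0.0381, 44),
    ("hsa-miR-142-5p", -1.54, 0.0239, 54),
    ("hsa-miR-192-5p", -1.56, 0.0440, 57),
    ("hsa-miR-155-5p", -1.43, 0.0186, 74),
    ("hsa-let-7g-5p", -1.43, 0.0351, 76),
]

_ICTAL_VS_INTERICTAL_DE = [
    ("hsa-miR-3202", 2.94, 0.0014, 1),
    ("hsa-miR-7855-5p", -2.69, 0.0033, 2),
    ("hsa-miR-6770-3p", 2.90, 0.0135, 3),
    ("hsa-miR-1538", -2.22, 0.0023, 4),
    ("hsa-miR-409-5p", -2.57, 0.0072, 5),
    ("hsa-miR-501-3p", -2.16, 0.0014, 6),
    ("hsa-miR-1299", 3.53, 0.0248, 7),
    ("hsa-miR-1271-5p", -2.60, 0.0187, 8),
    ("hsa-miR-4687-3p", -2.21, 0.0217, 9),
    ("hsa-miR-4743-5p", -2.07, 0.0135, 10),
    ("hsa-miR-1277-5p", 2.08, 0.0184, 11),
    ("hsa-miR-3180-3p", 2.51, 0.0351, 12),
    ("hsa-miR-4646-5p", -2.18, 0.0311, 13),
    ("hsa-miR-5581-3p", 2.14, 0.0251, 14),
    ("hsa-miR-6882-5p", 2.11, 0.0257, 15),
    ("hsa-miR-449a", 1.94, 0.0332, 16),
    ("hsa-miR-4473", 2.01, 0.0439, 17),
    ("hsa-miR-4775", 1.96, 0.0422, 18),
    ("hsa-miR-33b-3p", -1.92, 0.0411, 20),
    ("hsa-miR-99b-5p", -1.84, 0.0242, 21),
    ("hsa-miR-1270", 1.87, 0.0328, 22),
    ("hsa-miR-18b-5p", 1.94, 0.0463, 23),
    ("hsa-miR-6864-5p", 1.90, 0.0374, 24),
    ("hsa-miR-211-5p", 1.91, 0.0493, 25),
    ("hsa-miR-590-3p", 1.82, 0.0392, 31),
]

# (gene, measured mRNA log2FC, predicted node strength) — the published
# direction-consistent targets for each contrast
_INTERICTAL_VALIDATED = [
    ("PLCXD2", -1.337, 1),
    ("TNF", 2.814, -1),
    ("EGR1", 2.616, -1),
    ("EREG", 3.063, -1),
    ("CD83", 2.504, -1),
    ("NFKBIA", 1.861, -1),
    ("IER3", 1.810, -1),
    ("TNFAIP6", 2.464, -1),
    ("ID1", 1.723, -1),
    ("OSR2", 1.936, -1),
    ("NR4A2", 1.752, -1),
    ("CNTNAP3", 2.178, -1),
    ("FOSB", 1.524, -1),
    ("IL6", 1.826, -1),
    ("EGR3", 1.694, -1),
    ("DUSP1", 1.265, -1),
    ("SOCS3", 1.284, -1),
    ("SAT1", 1.147, -1),
    ("RGS1", 1.681, -1),
    ("PLAU", 1.312, -1),
    ("MIPOL1", 1.252, -1),
    ("JUNB", 1.059, -1),
    ("SGK1", 0.975, -1),
    ("MAP3K7CL", 0.878, -1),
    ("CXCL8", 2.806, -2),
    ("PLAUR", 1.428, -2),
    ("DUSP2", 1.521, -2),
    ("RBKS", 1.202, -2),
    ("GXYLT2", 1.888, -3),
    ("SOD2", 1.429, -4),
    ("SOCS1", 1.033, -4),
]

_ICTAL_VALIDATED = [
    ("RAB3B", -1.370, 3),
    ("LRRTM2", -1.051, 2),
    ("NOX5", -1.051, 1),
    ("FAT3", -1.003, 1),
    ("CBARP", -0.955, 1),
    ("BEND6", -0.890, 1),
    ("RPS27A", -0.675, 1),
    ("TBCA", -0.639, 1),
    ("FRG1B", -0.620, 1),
    ("ZNF730", 1.175, -1),
    ("ZNF704", 0.967, -1),
    ("MKI67", 0.826, -1),
]


def _de_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["feature_id", "fc_signed", "p_raw", "avg_rank_published"])


def interictal_vs_healthy_de() -> pd.DataFrame:
    """Published DE miRNA list for the interictal-vs-healthy contrast (31 rows)."""
    return _de_frame(_INTERICTAL_VS_HEALTHY_DE)


def ictal_vs_interictal_de() -> pd.DataFrame:
    """Published DE miRNA list for the ictal-vs-interictal contrast (25 rows)."""
    return _de_frame(_ICTAL_VS_INTERICTAL_DE)


def _validation_frame(rows) -> pd.DataFrame:
    return pd.DataFrame(rows, columns=["gene", "mrna_log2fc", "node_strength"])


def interictal_validated_targets() -> pd.DataFrame:
    """Published (mRNA log2FC, node strength) pairs, interictal vs healthy (31 genes)."""
    return _validation_frame(_INTERICTAL_VALIDATED)


def ictal_validated_targets() -> pd.DataFrame:
    """Published (mRNA log2FC, node strength) pairs, ictal vs interictal (12 genes)."""
    return _validation_frame(_ICTAL_VALIDATED)
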