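"""Published reference values for the eight cell lines originally used to
define the YAP1-high ("SCLC-Y") subtype.

These are the revised tumor classifications, neuroendocrine scores (CCLE
RNA-seq scale) and TP53/RB1/SMARCA4 genotype statuses reported for the eight
lines, plus the headline numbers of the reclassification analysis. They serve
as fixtures for desk-scale checks and as the expected values of the optional
external-data reproduction in :mod:`sclcy.external`.

Genotype status codes: WT = wild type, T = truncating mutation, M = missense
mutation.
"""

from __future__ import annotations

import pandas as pd

from .io import MutationTable

SCLC_Y_REFERENCE = pd.DataFrame(
    [
        # line,   depmap id,    revised classification,                         ne_score, TP53, RB1, SMARCA4
        ("H1341", "ACH-000129", "Small cell neuroendocrine carcinoma of the cervix", 0.2294, "WT", "WT", "WT"),
        ("DMS114", "ACH-000530", "SMARCA4-UT", 0.1365, "T", "WT", "T"),
        ("SBC5", "ACH-000670", "SMARCA4-UT", -0.2384, "M", "WT", "T"),
        ("H841", "ACH-000292", "SMARCA4-UT", -0.3397, "M", "WT", "T"),
        ("H2286", "ACH-000912", "Adenocarcinoma", -0.6746, "T", "WT", "M"),
        ("H157DM", "ACH-000921", "Squamous cell carcinoma", -0.7356, "T", "WT", "T"),
        ("H196", "ACH-000752", "Sarcomatoid malignancy", -0.7438, "M", "T", "WT"),
        ("SW1271", "ACH-000890", "SMARCA4-deficient malignancy", -0.8004, "M", "WT", "M"),
    ],
    columns=["cell_line", "depmap_id", "revised_classification", "ne_score", "TP53", "RB1", "SMARCA4"],
).set_index("cell_line")

#: Published headline numbers of the reclassification analysis, used by the
#: optional external-data checks.
PUBLISHED = {
    "n_sclc_y_lines": 8,
    "n_smarca4_mutant_sclc_y_lines": 6,
    "n_exclusive_y_genes": 26,
    "smarca4_protein_mrna_pearson_r": 0.53,
    "smarca4_protein_mrna_pearson_p": 1.5e-27,
    "ne_score_smarca4_group_mw_p": 0.0068,
    "smarca4_ut_cluster_lines": ("H841", "DMS114", "SBC5"),
    "smarca4_ut_cluster_size": 7,
    "source_driven_pc": 2,
    "retained_pcs": (1, 3, 4),
    "n_top_genes_per_pc": 50,
    "yap1_signature_size": 49,
    "smarca4ut_vs_nsclc_signature_size": 758,
    "group_sizes": {
        "SMARCA4-UT cluster": 7,
        "SMARCA4 mutant NSCLC": 31,
        "SMARCA4 proficient NSCLC": 88,
        "SCLC-A/N/P": 43,
    },
}

# Representative protein changes for encoding the printed T/M statuses as
# variant records (the published table prints only the status letters; the two
# SMARCA4 changes below are the documented examples for H841 and SW1271).
_STATUS_RECORDS = {
    "T": ("Nonsense_Mutation", "p.Q100*"),
    "M": ("Missense_Mutation", "p.A100T"),
}
_KNOWN_CHANGES = {
    ("H841", "SMARCA4"): ("Nonsense_Mutation", "p.R1077*"),
    ("SW1271", "SMARCA4"): ("Missense_Mutation", "p.G1232S"),
}


def reference_mutation_table() -> MutationTable:
    """The printed TP53/RB1/SMARCA4 statuses of the eight lines encoded as a
    variant-record fixture (one record per non-WT status)."""
    rows = []
    for line, row in SCLC_Y_REFERENCE.iterrows():
        for gene in ("TP53", "RB1", "SMARCA4"):
            status = row[gene]
            if status == "WT":
                continue
            cls, change = _KNOWN_CHANGES.get((line, gene), _STATUS_RECORDS[status])
            rows.append((line, gene, cls, change))
    return MutationTable(
        records=pd.DataFrame(
            rows, columns=["sample", "gene", "variant_classification", "protein_change"]
        )
    )


def reference_ne_scores() -> pd.Series:
    """Published NE scores of the eight lines (CCLE RNA-seq scale)."""
    return SCLC_Y_REFERENCE["ne_score"].copy()


def reference_smarca4_status() -> pd.Series:
    """Published SMARCA4 status (WT/T/M) of the eight lines."""
    return SCLC_Y_REFERENCE["SMARCA4"].copy()
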