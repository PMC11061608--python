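"""Correlation-based neuroendocrine (NE) scoring.

A sample's NE score is half the difference between its Pearson correlation
with a neuroendocrine reference mean profile and with a non-neuroendocrine
reference mean profile, computed over the genes of a 50-gene-style signature:

    score = (r_NE - r_nonNE) / 2,   score in [-1, 1].

The signature (gene classes and the two reference mean vectors) is an external
input; signature genes absent from the matrix are dropped symmetrically from
the sample vector and both reference vectors.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSignature, ValidationError


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    return float(stats.pearsonr(x, y).statistic)


def compute_ne_scores(
    expr: ExpressionMatrix,
    signature: GeneSignature,
    min_coverage: float = 0.8,
    method: str = "pearson",
) -> pd.DataFrame:
    """Score every sample of ``expr`` against the signature's reference profiles.

    Returns a DataFrame indexed by sample with columns ``score``, ``r_ne``,
    ``r_nonne`` and ``n_genes_used``. Requires both NE and NON_NE classes,
    reference profiles, and at least ``min_coverage`` of the classed signature
    genes present in the matrix. A zero-variance sample vector over the
    signature genes yields a missing score with a warning.
    """
    if method not in ("pearson", "spearman"):
        raise ValueError(f"unknown correlation method {method!r}")
    classed = [g for g in signature.genes if signature.members[g] in ("NE", "NON_NE")]
    if not signature.genes_of_class("NE") or not signature.genes_of_class("NON_NE"):
        raise ValidationError("signature must contain both NE and NON_NE genes")
    present = [g for g in classed if g in expr.values.index]
    coverage = len(present) / len(classed)
    if coverage < min_coverage:
        missing = sorted(set(classed) - set(present))
        raise ValidationError(
            f"only {coverage:.0%} of signature genes present (< {min_coverage:.0%}); "
            f"missing: {missing}"
        )
    prof = signature.reference_profiles.loc[present]
    mean_ne = prof["mean_ne"].to_numpy()
    mean_nonne = prof["mean_nonne"].to_numpy()
    if np.std(mean_ne) == 0 or np.std(mean_nonne) == 0:
        raise ValidationError("reference profile has zero variance over available genes")
    sub = expr.values.loc[present]
    if method == "spearman":
        sub = sub.rank(axis=0)
        mean_ne = stats.rankdata(mean_ne)
        mean_nonne = stats.rankdata(mean_nonne)
    rows = []
    for sample in expr.sample_ids:
        vec = sub[sample].to_numpy(float)
        if np.std(vec) == 0:
            warnings.warn(
                f"sample {sample!r} has zero variance over signature genes; score undefined"
            )
            rows.append((sample, np.nan, np.nan, np.nan, len(present)))
            continue
        r_ne = _pearson(vec, mean_ne)
        r_nonne = _pearson(vec, mean_nonne)
        rows.append((sample, (r_ne - r_nonne) / 2.0, r_ne, r_nonne, len(present)))
    out = pd.DataFrame(
        rows, columns=["sample", "score", "r_ne", "r_nonne", "n_genes_used"]
    ).set_index("sample")
    out["n_genes_used"] = out["n_genes_used"].astype(int)
    return out
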