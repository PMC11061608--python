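"""Cross-cohort integration: merge on shared genes, quantile-normalize,
z-score genes.

Quantile normalization maps every sample's values onto the cross-sample mean
of order statistics, so afterwards every sample has an identical sorted
vector; ties within a sample receive the mean of the reference values they
span. Z-scoring centres every gene row and scales it to unit population
standard deviation.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, MergedMatrix, ValidationError


def merge_cohorts(
    a: ExpressionMatrix,
    b: ExpressionMatrix,
    labels: tuple[str, str] = ("cohort_a", "cohort_b"),
) -> MergedMatrix:
    """Column-concatenate two cohorts on their shared genes (in ``a``'s order),
    tagging every sample with its source label."""
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise ValidationError("cohorts share no genes")
    overlap = set(a.sample_ids) & set(b.sample_ids)
    if overlap:
        raise ValidationError(f"duplicate sample ids across cohorts: {sorted(overlap)}")
    values = pd.concat([a.values.loc[shared], b.values.loc[shared]], axis=1)
    meta_parts = []
    for em, label in ((a, labels[0]), (b, labels[1])):
        meta = (
            em.sample_meta.copy()
            if em.sample_meta is not None
            else pd.DataFrame(index=em.sample_ids)
        )
        meta["source_cohort"] = label
        meta_parts.append(meta)
    meta = pd.concat(meta_parts)
    return MergedMatrix(values=values, sample_meta=meta)


def quantile_normalize(m: MergedMatrix) -> MergedMatrix:
    """Force every sample onto the common reference of rank-wise means."""
    if m.n_samples < 2:
        raise ValidationError("quantile normalization needs >= 2 samples")
    X = m.values.to_numpy(float)
    ref = np.sort(X, axis=0).mean(axis=1)
    out = np.empty_like(X)
    for j in range(X.shape[1]):
        col = X[:, j]
        order = np.argsort(col, kind="mergesort")
        assigned = np.empty_like(col)
        assigned[order] = ref
        # tied values get the mean of the reference values they span
        s = pd.Series(assigned).groupby(col).transform("mean")
        out[:, j] = s.to_numpy()
    values = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return MergedMatrix(values=values, sample_meta=m.sample_meta)


def zscore_genes(m: MergedMatrix, ddof: int = 0) -> MergedMatrix:
    """Centre and unit-scale every gene row (population sd by default);
    zero-variance rows are dropped with a warning."""
    if m.n_samples < 2:
        raise ValidationError("z-scoring needs >= 2 samples")
    X = m.values
    sd = X.std(axis=1, ddof=ddof)
    flat = sd == 0
    if flat.any():
        warnings.warn(f"dropping {int(flat.sum())} zero-variance gene row(s)")
        X = X.loc[~flat]
        sd = sd.loc[~flat]
    values = X.sub(X.mean(axis=1), axis=0).div(sd, axis=0)
    return MergedMatrix(values=values, sample_meta=m.sample_meta)
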