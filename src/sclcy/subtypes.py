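"""Molecular subtype assignment by the dominant lineage transcription factor.

Each sample is called A, N, P or Y according to which of ASCL1, NEUROD1,
POU2F3 or YAP1 has the highest expression on the matrix's given log scale
(no per-gene standardisation). Exact ties are broken by the declared gene
order and flagged.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, normalize_gene

SUBTYPE_CODES = ("A", "N", "P", "Y")
DEFAULT_TF_GENES = ("ASCL1", "NEUROD1", "POU2F3", "YAP1")


@dataclass
class SubtypePartition:
    """Per-sample subtype call with the four TF values and a tie flag.

    ``table`` is indexed by sample with columns ``subtype``, one per TF gene,
    and ``tie``.
    """

    table: pd.DataFrame
    tf_genes: tuple[str, ...]

    @property
    def subtype_of(self) -> pd.Series:
        return self.table["subtype"]

    def samples_of(self, subtype: str) -> list[str]:
        return list(self.table.index[self.table["subtype"] == subtype])

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)


def assign_subtypes(
    expr: ExpressionMatrix, tf_genes: Sequence[str] = DEFAULT_TF_GENES
) -> SubtypePartition:
    """Call one subtype per sample as the arg-max over the four TF genes.

    Ties take the first maximal TF in the declared order and set ``tie=True``.
    Raises ``KeyError`` naming any TF gene missing from the matrix.
    """
    tf_genes = tuple(normalize_gene(g) for g in tf_genes)
    if len(tf_genes) != len(SUBTYPE_CODES):
        raise ValueError(f"expected {len(SUBTYPE_CODES)} TF genes, got {len(tf_genes)}")
    for gene in tf_genes:
        if gene not in expr.values.index:
            raise KeyError(f"transcription factor gene {gene!r} not in expression matrix")
    block = expr.values.loc[list(tf_genes)]  # 4 x samples
    arr = block.to_numpy()
    idx = np.argmax(arr, axis=0)  # first maximum wins -> declared-order tie-break
    ties = (arr == arr.max(axis=0, keepdims=True)).sum(axis=0) > 1
    table = block.T.copy()
    table.insert(0, "subtype", [SUBTYPE_CODES[i] for i in idx])
    table["tie"] = ties
    return SubtypePartition(table=table, tf_genes=tf_genes)
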