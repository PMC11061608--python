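"""Variant classification, per-subtype mutation prevalence and the
subtype-exclusive gene screen.

The screen counts, for every gene and subtype, the fraction of that subtype's
samples carrying at least one record for the gene (a sample counts once per
gene no matter how many variants it carries). Genes above the prevalence
threshold in exactly one subtype are that subtype's exclusive set; the rest of
the prevalent union is partitioned into Venn cells keyed by the exact subtype
combination.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .io import (
    MISSENSE_TERMS,
    MUTATION_VOCABULARY,
    TRUNCATING_TERMS,
    MutationTable,
    normalize_gene,
)
from .subtypes import SubtypePartition


class MutationClass(str, Enum):
    TRUNCATING = "TRUNCATING"
    MISSENSE = "MISSENSE"
    OTHER = "OTHER"
    WT = "WT"


# worst-first precedence for per-(sample, gene) summarisation
_PRECEDENCE = {
    MutationClass.TRUNCATING: 0,
    MutationClass.MISSENSE: 1,
    MutationClass.OTHER: 2,
    MutationClass.WT: 3,
}


def classify_variant(variant_classification: str, protein_change: str = "") -> MutationClass:
    """Map a raw variant-classification term to TRUNCATING / MISSENSE / OTHER.

    Nonsense, frameshift (ins or del), splice-site and nonstop terms are
    truncating; missense is missense; every other coding term — and any term
    outside the declared vocabulary, with a warning — is OTHER. Absence of a
    record (WT) is handled by the callers, not here.
    """
    term = str(variant_classification)
    if term in TRUNCATING_TERMS:
        return MutationClass.TRUNCATING
    if term in MISSENSE_TERMS:
        return MutationClass.MISSENSE
    if term not in MUTATION_VOCABULARY:
        warnings.warn(f"unknown variant classification {term!r} treated as OTHER")
    return MutationClass.OTHER


@dataclass
class ExclusiveMutationSets:
    """Venn decomposition of the per-subtype prevalent gene sets."""

    prevalent: dict[str, frozenset[str]]
    exclusive: dict[str, frozenset[str]]
    shared: dict[tuple[str, ...], frozenset[str]]
    threshold: float | None = None

    def venn_cells(self) -> dict[tuple[str, ...], frozenset[str]]:
        cells = {(s,): genes for s, genes in self.exclusive.items() if genes}
        cells.update({combo: genes for combo, genes in self.shared.items() if genes})
        return cells


def prevalent_genes(
    mut: MutationTable,
    partition: SubtypePartition,
    threshold: float = 0.5,
    strict: bool = False,
) -> dict[str, frozenset[str]]:
    """Genes mutated in at least (or, with ``strict``, more than) the given
    fraction of each subtype's samples.

    Mutated samples absent from the partition are dropped with a warning;
    empty subtypes yield empty sets with a warning.
    """
    known = set(partition.sample_ids)
    rec = mut.records
    extraneous = set(rec["sample"]) - known
    if extraneous:
        warnings.warn(
            f"dropping {len(extraneous)} mutated sample(s) absent from the partition: "
            f"{sorted(extraneous)}"
        )
        rec = rec[rec["sample"].isin(known)]
    hits = rec.drop_duplicates(subset=["sample", "gene"])
    out: dict[str, frozenset[str]] = {}
    for subtype in sorted(set(partition.subtype_of)):
        members = partition.samples_of(subtype)
        if not members:
            warnings.warn(f"subtype {subtype} has no samples; empty prevalent set")
            out[subtype] = frozenset()
            continue
        sub_hits = hits[hits["sample"].isin(members)]
        counts = sub_hits.groupby("gene")["sample"].nunique()
        frac = counts / len(members)
        keep = frac > threshold if strict else frac >= threshold
        out[subtype] = frozenset(frac.index[keep])
    return out


def exclusive_genes(
    prevalent: Mapping[str, Iterable[str]], threshold: float | None = None
) -> ExclusiveMutationSets:
    """Partition the union of prevalent sets into exclusive and shared cells."""
    prev = {s: frozenset(normalize_gene(g) for g in genes) for s, genes in prevalent.items()}
    union = frozenset().union(*prev.values()) if prev else frozenset()
    membership: dict[str, tuple[str, ...]] = {
        gene: tuple(sorted(s for s in prev if gene in prev[s])) for gene in union
    }
    exclusive = {
        s: frozenset(g for g, combo in membership.items() if combo == (s,)) for s in prev
    }
    shared: dict[tuple[str, ...], frozenset[str]] = {}
    for gene, combo in membership.items():
        if len(combo) > 1:
            shared.setdefault(combo, frozenset())
            shared[combo] = shared[combo] | {gene}
    return ExclusiveMutationSets(
        prevalent=prev, exclusive=exclusive, shared=shared, threshold=threshold
    )


def genotype_summary(
    mut: MutationTable, samples: Sequence[str], genes: Sequence[str]
) -> pd.DataFrame:
    """Worst mutation class per (sample, gene), precedence
    TRUNCATING > MISSENSE > OTHER > WT; absence of records is WT."""
    genes = [normalize_gene(g) for g in genes]
    samples = [str(s) for s in samples]
    out = pd.DataFrame(MutationClass.WT.value, index=samples, columns=genes)
    rec = mut.records
    rec = rec[rec["sample"].isin(samples) & rec["gene"].isin(genes)]
    for (sample, gene), group in rec.groupby(["sample", "gene"]):
        classes = [
            classify_variant(vc, pc)
            for vc, pc in zip(group["variant_classification"], group["protein_change"])
        ]
        worst = min(classes, key=_PRECEDENCE.__getitem__)
        out.loc[sample, gene] = worst.value
    return out
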