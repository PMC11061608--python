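"""Synthetic cohort generator with planted ground truth.

Emulates the statistical structure the reclassification pipeline assumes:

* four molecular subtypes, each with an elevated dominant transcription
  factor (ASCL1 / NEUROD1 / POU2F3 / YAP1);
* correlated neuroendocrine (NE) and non-NE signature-gene blocks — high-NE
  subtypes (A, N) gain on NE genes and lose on non-NE genes, low-NE subtypes
  (P, Y) the reverse;
* a SMARCA4-deficient subgroup inside subtype Y with reduced SMARCA4
  expression and a guaranteed truncating SMARCA4 record, so genotype and
  expression deficiency coincide as they do in the real cell lines;
* an additive two-source batch shift on a seeded random gene subset, with
  sources alternating within each subtype (balanced, orthogonal to biology);
* Bernoulli mutation tables at configured per-subtype prevalences, with
  planted subtype-exclusive genes recorded in the truth object.

All draws come from independent child generators spawned from a single seed
in a fixed, documented order (expression noise, batch gene subset, deficient
subset, mutations), so enlarging the gene panel never perturbs the mutation
draws.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io import AnnotationTable, ExpressionMatrix, GeneSignature, MutationTable
from .subtypes import DEFAULT_TF_GENES, SUBTYPE_CODES

NE_HIGH_SUBTYPES = ("A", "N")

_DEFAULT_PREVALENCE: dict[str, dict[str, float]] = {
    "A": {"TP53": 0.9, "RB1": 0.9},
    "N": {"TP53": 0.9, "RB1": 0.9},
    "P": {"TP53": 0.9, "RB1": 0.9},
    "Y": {"TP53": 0.85},
}


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic cohort; defaults mirror the cohort structure the
    pipeline was designed around (an A-dominant SCLC panel with eight
    YAP1-high lines, three quarters of them SMARCA4-deficient).

    Effects are additive on the log-abundance scale.
    """

    n_per_subtype: dict[str, int] = field(
        default_factory=lambda: {"A": 16, "N": 12, "P": 8, "Y": 8}
    )
    tf_effect: float = 3.0
    ne_block_effect: float = 2.0
    smarca4_fraction_of_y: float = 0.75
    smarca4_expression_drop: float = 2.0
    batch_fraction: float = 0.3
    batch_effect: float = 2.0
    mutation_prevalence: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(g) for s, g in _DEFAULT_PREVALENCE.items()}
    )
    exclusive_threshold: float = 0.5
    noise_sd: float = 1.0
    n_background_genes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if any(n < 0 for n in self.n_per_subtype.values()):
            raise ValueError("subtype counts must be >= 0")
        if sum(self.n_per_subtype.get(s, 0) for s in SUBTYPE_CODES) == 0:
            raise ValueError("at least one subtype must have samples")
        if not 0 <= self.smarca4_fraction_of_y <= 1:
            raise ValueError("smarca4_fraction_of_y must lie in [0, 1]")
        if not 0 <= self.batch_fraction <= 1:
            raise ValueError("batch_fraction must lie in [0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        for subtype, genes in self.mutation_prevalence.items():
            for gene, p in genes.items():
                if not 0 <= p <= 1:
                    raise ValueError(f"prevalence {p} for {gene} in {subtype} outside [0, 1]")


@dataclass
class SyntheticTruth:
    """Planted ground truth accompanying a simulated cohort."""

    per_sample: pd.DataFrame  # index sample: true_subtype, true_batch, smarca4_deficient
    planted_exclusive_genes: dict[str, frozenset[str]]
    smarca4_deficient: frozenset[str]
    signature: GeneSignature
    batch_genes: frozenset[str] = frozenset()

    @property
    def true_subtype(self) -> pd.Series:
        return self.per_sample["true_subtype"]

    @property
    def true_batch(self) -> pd.Series:
        return self.per_sample["true_batch"]


def default_ne_signature(ne_block_effect: float) -> GeneSignature:
    """25 NE + 25 non-NE synthetic genes; reference profiles equal the
    configured block means, mirroring the shape of the real 50-gene set."""
    ne = [f"NESIG{i:02d}" for i in range(1, 26)]
    nonne = [f"NONNE{i:02d}" for i in range(1, 26)]
    members = {**{g: "NE" for g in ne}, **{g: "NON_NE" for g in nonne}}
    e = float(ne_block_effect)
    prof = pd.DataFrame(
        {
            "mean_ne": [e] * 25 + [-e] * 25,
            "mean_nonne": [-e] * 25 + [e] * 25,
        },
        index=ne + nonne,
    )
    return GeneSignature(name="synthetic_ne50", members=members, reference_profiles=prof)


def tf_signature() -> GeneSignature:
    """The four subtype transcription factors as a plain member signature."""
    return GeneSignature(name="tf4", members={g: "MEMBER" for g in DEFAULT_TF_GENES})


def _effective_prevalence(config: SimulationConfig) -> dict[str, dict[str, float]]:
    """Configured prevalences plus the forced SMARCA4 records of the deficient
    subset of subtype Y."""
    prev = {s: dict(g) for s, g in config.mutation_prevalence.items()}
    f = config.smarca4_fraction_of_y
    if config.n_per_subtype.get("Y", 0) > 0 and f > 0:
        p_cfg = prev.get("Y", {}).get("SMARCA4", 0.0)
        prev.setdefault("Y", {})["SMARCA4"] = f + (1 - f) * p_cfg
    return prev


def planted_exclusive_genes(config: SimulationConfig) -> dict[str, frozenset[str]]:
    """Genes whose effective prevalence exceeds the exclusive threshold in
    exactly one subtype."""
    prev = _effective_prevalence(config)
    above: dict[str, set[str]] = {s: set() for s in SUBTYPE_CODES}
    for subtype, genes in prev.items():
        for gene, p in genes.items():
            if p > config.exclusive_threshold and config.n_per_subtype.get(subtype, 0) > 0:
                above[subtype].add(gene)
    out: dict[str, frozenset[str]] = {}
    for subtype in SUBTYPE_CODES:
        others = set().union(*(above[s] for s in SUBTYPE_CODES if s != subtype))
        out[subtype] = frozenset(above[subtype] - others)
    return out


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, MutationTable, AnnotationTable, SyntheticTruth]:
    """Generate (expression, mutations, annotations, truth) for one cohort.

    Identical configs (same seed) produce identical outputs.
    """
    ss = np.random.SeedSequence(config.seed)
    rng_expr, rng_batch_genes, rng_deficient, rng_mut = (
        np.random.default_rng(child) for child in ss.spawn(4)
    )

    signature = default_ne_signature(config.ne_block_effect)
    ne_genes = signature.genes_of_class("NE")
    nonne_genes = signature.genes_of_class("NON_NE")
    tf_genes = list(DEFAULT_TF_GENES)
    background = [f"BG{i:04d}" for i in range(1, config.n_background_genes + 1)]
    genes = tf_genes + ["SMARCA4"] + ne_genes + nonne_genes + background

    samples: list[str] = []
    subtype_of: dict[str, str] = {}
    batch_of: dict[str, str] = {}
    for subtype in SUBTYPE_CODES:
        for i in range(config.n_per_subtype.get(subtype, 0)):
            name = f"{subtype}{i + 1:03d}"
            samples.append(name)
            subtype_of[name] = subtype
            batch_of[name] = "source1" if i % 2 == 0 else "source2"

    X = rng_expr.normal(0.0, config.noise_sd, size=(len(genes), len(samples)))
    values = pd.DataFrame(X, index=genes, columns=samples)

    gene_pos = {g: i for i, g in enumerate(genes)}
    tf_of_subtype = dict(zip(SUBTYPE_CODES, tf_genes))
    e = config.ne_block_effect
    for j, sample in enumerate(samples):
        st = subtype_of[sample]
        values.iloc[gene_pos[tf_of_subtype[st]], j] += config.tf_effect
        sign = 1.0 if st in NE_HIGH_SUBTYPES else -1.0
        values.iloc[[gene_pos[g] for g in ne_genes], j] += sign * e
        values.iloc[[gene_pos[g] for g in nonne_genes], j] -= sign * e

    # The source shift hits background genes only: subtype calling and the
    # NE/non-NE blocks are the planted biology, and the generator keeps them
    # orthogonal to the technical axis (see the methods note).
    n_batch_genes = min(
        int(round(config.batch_fraction * len(genes))), len(background)
    )
    bg_offset = len(genes) - len(background)
    batch_gene_idx = bg_offset + rng_batch_genes.choice(
        len(background), size=n_batch_genes, replace=False
    )
    batch_gene_set = frozenset(genes[i] for i in batch_gene_idx)
    source2 = [j for j, s in enumerate(samples) if batch_of[s] == "source2"]
    if source2 and n_batch_genes:
        values.iloc[batch_gene_idx, source2] += config.batch_effect

    y_samples = [s for s in samples if subtype_of[s] == "Y"]
    n_deficient = int(round(config.smarca4_fraction_of_y * len(y_samples)))
    deficient = frozenset(
        rng_deficient.choice(y_samples, size=n_deficient, replace=False)
    ) if n_deficient else frozenset()
    for s in deficient:
        values.loc["SMARCA4", s] -= config.smarca4_expression_drop

    records: list[tuple[str, str, str, str]] = []
    classifications = ("Missense_Mutation", "Nonsense_Mutation", "Frame_Shift_Del")
    class_probs = (0.5, 0.3, 0.2)
    for sample in samples:
        st = subtype_of[sample]
        if sample in deficient:
            records.append((sample, "SMARCA4", "Nonsense_Mutation", "p.R1077*"))
        for gene in sorted(config.mutation_prevalence.get(st, {})):
            p = config.mutation_prevalence[st][gene]
            if gene == "SMARCA4" and sample in deficient:
                continue  # already carries the forced truncating record
            if rng_mut.random() < p:
                cls = classifications[rng_mut.choice(3, p=class_probs)]
                pos = int(rng_mut.integers(50, 1500))
                change = f"p.A{pos}T" if cls == "Missense_Mutation" else f"p.Q{pos}*"
                records.append((sample, gene, cls, change))
    mut = MutationTable(
        records=pd.DataFrame(
            records, columns=["sample", "gene", "variant_classification", "protein_change"]
        )
    )

    ann = pd.DataFrame(
        {
            "source_cohort": [batch_of[s] for s in samples],
            "histology": ["SCLC"] * len(samples),
            "reference_class": [
                "SMARCA4-UT" if s in deficient else "SCLC" for s in samples
            ],
        },
        index=samples,
    )
    annotations = AnnotationTable(table=ann)

    expr = ExpressionMatrix(values=values, sample_meta=ann.copy())
    truth = SyntheticTruth(
        per_sample=pd.DataFrame(
            {
                "true_subtype": [subtype_of[s] for s in samples],
                "true_batch": [batch_of[s] for s in samples],
                "smarca4_deficient": [s in deficient for s in samples],
            },
            index=samples,
        ),
        planted_exclusive_genes=planted_exclusive_genes(config),
        smarca4_deficient=deficient,
        signature=signature,
        batch_genes=batch_gene_set,
    )
    return expr, mut, annotations, truth
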