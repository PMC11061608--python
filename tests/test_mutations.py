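"""Variant classification, prevalence screen, Venn decomposition, genotype
summary — each checked against brute-force oracles."""

import itertools

import numpy as np
import pandas as pd
import pytest

from sclcy import (
    MutationClass,
    MutationTable,
    SubtypePartition,
    classify_variant,
    exclusive_genes,
    genotype_summary,
    prevalent_genes,
)
from sclcy.reference import reference_mutation_table, SCLC_Y_REFERENCE


def _partition(mapping):
    table = pd.DataFrame({"subtype": pd.Series(mapping)})
    table["tie"] = False
    return SubtypePartition(table=table, tf_genes=("ASCL1", "NEUROD1", "POU2F3", "YAP1"))


def _mut(rows):
    return MutationTable(
        records=pd.DataFrame(
            rows, columns=["sample", "gene", "variant_classification", "protein_change"]
        )
    )


@pytest.mark.parametrize(
    "term,change,expected",
    [
        ("Nonsense_Mutation", "p.R1077*", MutationClass.TRUNCATING),
        ("Frame_Shift_Ins", "p.T910fs", MutationClass.TRUNCATING),
        ("Frame_Shift_Del", "p.T910fs", MutationClass.TRUNCATING),
        ("Splice_Site", "p.X300_splice", MutationClass.TRUNCATING),
        ("Nonstop_Mutation", "p.*1648L", MutationClass.TRUNCATING),
        ("Missense_Mutation", "p.G1232S", MutationClass.MISSENSE),
        ("In_Frame_Del", "p.K745del", MutationClass.OTHER),
        ("Silent", "p.L100L", MutationClass.OTHER),
    ],
)
def test_classify_variant(term, change, expected):
    assert classify_variant(term, change) is expected


def test_unknown_term_is_other_with_warning():
    with pytest.warns(UserWarning, match="unknown variant classification"):
        assert classify_variant("Weird_Term", "") is MutationClass.OTHER


def test_prevalence_six_of_eight_included_at_half_threshold():
    samples = {f"y{i}": "Y" for i in range(8)}
    part = _partition(samples)
    rows = [(f"y{i}", "SMARCA4", "Nonsense_Mutation", f"p.Q{i}*") for i in range(6)]
    prevalent = prevalent_genes(_mut(rows), part, threshold=0.5)
    assert "SMARCA4" in prevalent["Y"]  # 0.75 >= 0.5
    strict = prevalent_genes(_mut(rows), part, threshold=0.75, strict=True)
    assert "SMARCA4" not in strict["Y"]  # 0.75 is not > 0.75


def test_empty_mutation_table_gives_empty_sets():
    part = _partition({"a1": "A", "y1": "Y"})
    prevalent = prevalent_genes(_mut([]), part)
    assert all(len(g) == 0 for g in prevalent.values())


def test_prevalence_counts_a_sample_once_per_gene():
    part = _partition({"s1": "A", "s2": "A"})
    rows = [
        ("s1", "TP53", "Missense_Mutation", "p.R175H"),
        ("s1", "TP53", "Nonsense_Mutation", "p.Q192*"),
    ]
    # prevalence is 1/2 mutated sample, not 2/2 variants
    assert "TP53" in prevalent_genes(_mut(rows), part, threshold=0.5)["A"]
    assert "TP53" not in prevalent_genes(_mut(rows), part, threshold=0.5, strict=True)["A"]


def test_extraneous_samples_dropped_with_warning():
    part = _partition({"s1": "A"})
    rows = [("ghost", "TP53", "Missense_Mutation", "p.R175H")]
    with pytest.warns(UserWarning, match="absent from the partition"):
        prevalent = prevalent_genes(_mut(rows), part)
    assert prevalent["A"] == frozenset()


def test_prevalence_matches_brute_force_count(rng):
    """Toy table: sets match an exhaustive count over all (gene, subtype) pairs."""
    subtypes = ["A", "N", "P"]
    samples = {f"s{i}": subtypes[i % 3] for i in range(12)}
    part = _partition(samples)
    genes = [f"G{k}" for k in range(5)]
    rows = []
    for s in samples:
        for g in genes:
            if rng.random() < 0.4:
                rows.append((s, g, "Missense_Mutation", f"p.A{rng.integers(1,999)}T"))
    mut = _mut(rows)
    for threshold in (0.25, 0.5):
        for strict in (False, True):
            prevalent = prevalent_genes(mut, part, threshold=threshold, strict=strict)
            for st in subtypes:
                members = [s for s, v in samples.items() if v == st]
                for g in genes:
                    n_hit = sum(
                        any(r[0] == s and r[1] == g for r in rows) for s in members
                    )
                    frac = n_hit / len(members)
                    expected = frac > threshold if strict else frac >= threshold
                    assert (g in prevalent[st]) == expected


def test_exclusive_identical_sets_yield_empty_exclusives():
    prevalent = {s: {"TP53", "RB1"} for s in "ANPY"}
    sets = exclusive_genes(prevalent)
    assert all(len(g) == 0 for g in sets.exclusive.values())
    assert sets.shared[("A", "N", "P", "Y")] == frozenset({"TP53", "RB1"})


def test_exclusive_venn_example():
    prevalent = {"Y": {"SMARCA4", "TP53"}, "A": {"TP53"}, "N": {"TP53"}, "P": set()}
    sets = exclusive_genes(prevalent)
    assert sets.exclusive["Y"] == frozenset({"SMARCA4"})
    assert sets.shared[("A", "N", "Y")] == frozenset({"TP53"})


def test_exclusive_enumerates_all_membership_patterns():
    """One gene per nonempty subset of {A,N,P,Y}: every Venn cell lands right."""
    subtypes = ("A", "N", "P", "Y")
    prevalent = {s: set() for s in subtypes}
    gene_of = {}
    for r in range(1, 5):
        for combo in itertools.combinations(subtypes, r):
            gene = "G_" + "".join(combo)
            gene_of[combo] = gene
            for s in combo:
                prevalent[s].add(gene)
    sets = exclusive_genes(prevalent)
    for combo, gene in gene_of.items():
        if len(combo) == 1:
            assert gene in sets.exclusive[combo[0]]
        else:
            assert gene in sets.shared[combo]
    # partition conservation: Venn cells cover the union exactly once
    union = set().union(*prevalent.values())
    cells = list(sets.venn_cells().values())
    assert sum(len(c) for c in cells) == len(union)
    assert set().union(*cells) == union


def test_enlarging_another_subtypes_set_never_grows_exclusive():
    prevalent = {"A": {"G1", "G2"}, "N": {"G3"}, "P": set(), "Y": set()}
    base = exclusive_genes(prevalent).exclusive["A"]
    bigger = {**prevalent, "N": prevalent["N"] | {"G2"}}
    grown = exclusive_genes(bigger).exclusive["A"]
    assert grown <= base


def test_genotype_precedence_truncating_beats_missense():
    rows = [
        ("s1", "SMARCA4", "Missense_Mutation", "p.G1232S"),
        ("s1", "SMARCA4", "Nonsense_Mutation", "p.R1077*"),
    ]
    table = genotype_summary(_mut(rows), ["s1"], ["SMARCA4"])
    assert table.loc["s1", "SMARCA4"] == "TRUNCATING"


def test_genotype_absent_record_is_wt():
    table = genotype_summary(_mut([]), ["s1"], ["TP53"])
    assert table.loc["s1", "TP53"] == "WT"


def test_published_genotype_fixture_has_six_smarca4_mutant_lines():
    mut = reference_mutation_table()
    table = genotype_summary(
        mut, list(SCLC_Y_REFERENCE.index), ["TP53", "RB1", "SMARCA4"]
    )
    assert (table["SMARCA4"] != "WT").sum() == 6
    assert table.loc["H841", "SMARCA4"] == "TRUNCATING"
    assert table.loc["SW1271", "SMARCA4"] == "MISSENSE"


def test_genotype_summary_matches_brute_force_precedence_scan(rng):
    samples = [f"s{i}" for i in range(5)]
    genes = ["TP53", "RB1", "SMARCA4"]
    terms = ["Missense_Mutation", "Nonsense_Mutation", "Silent", "Frame_Shift_Del"]
    rows = []
    for _ in range(25):
        rows.append(
            (
                samples[rng.integers(5)],
                genes[rng.integers(3)],
                terms[rng.integers(4)],
                f"p.A{rng.integers(1, 2000)}T",
            )
        )
    mut = _mut(rows)
    table = genotype_summary(mut, samples, genes)
    rank = {"TRUNCATING": 0, "MISSENSE": 1, "OTHER": 2, "WT": 3}
    term_class = {
        "Missense_Mutation": "MISSENSE",
        "Nonsense_Mutation": "TRUNCATING",
        "Frame_Shift_Del": "TRUNCATING",
        "Silent": "OTHER",
    }
    for s in samples:
        for g in genes:
            hits = [term_class[r[2]] for r in mut.records.itertuples(index=False)
                    if r[0] == s and r[1] == g]
            expected = min(hits, key=rank.__getitem__) if hits else "WT"
            assert table.loc[s, g] == expected
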