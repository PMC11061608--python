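"""Hierarchical clustering, anchor labelling and the batch-PC gene screen."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from sclcy import (
    AnnotationTable,
    GeneSignature,
    SimulationConfig,
    ValidationError,
    batch_aware_gene_selection,
    hcluster_signature,
    label_clusters,
    simulate_cohort,
    tf_signature,
)


def _three_group_cohort(seed):
    cfg = SimulationConfig(
        seed=seed, tf_effect=4.0, noise_sd=0.5, batch_effect=0.0,
        n_per_subtype={"A": 10, "N": 10, "P": 10, "Y": 0},
        smarca4_fraction_of_y=0.0,
    )
    return simulate_cohort(cfg)


def test_k1_puts_all_samples_in_one_cluster():
    expr, _, _, _ = _three_group_cohort(3)
    model = hcluster_signature(expr, tf_signature(), k=1)
    assert model.assignment.nunique() == 1


def test_k_larger_than_n_errors():
    expr, _, _, _ = _three_group_cohort(3)
    with pytest.raises(ValidationError, match="exceeds"):
        hcluster_signature(expr, tf_signature(), k=expr.n_samples + 1)


def test_planted_three_groups_recovered_exactly():
    expr, _, _, truth = _three_group_cohort(3)
    model = hcluster_signature(expr, tf_signature(), k=3)
    ari = adjusted_rand_score(
        truth.true_subtype.loc[model.samples], model.assignment.loc[model.samples]
    )
    assert ari == 1.0


def test_clustering_invariant_to_sample_order():
    expr, _, _, _ = _three_group_cohort(4)
    from sclcy import ExpressionMatrix

    perm = list(expr.values.columns[::-1])
    shuffled = ExpressionMatrix(values=expr.values[perm], sample_meta=expr.sample_meta)
    a = hcluster_signature(expr, tf_signature(), k=3)
    b = hcluster_signature(shuffled, tf_signature(), k=3)
    assert (a.assignment == b.assignment.loc[a.assignment.index]).all()
    assert np.allclose(a.linkage, b.linkage)


def test_linkage_heights_nondecreasing_and_merge_count():
    expr, _, _, _ = _three_group_cohort(5)
    model = hcluster_signature(expr, tf_signature(), k=3)
    heights = model.linkage[:, 2]
    assert (np.diff(heights) >= -1e-12).all()
    assert model.linkage.shape[0] == expr.n_samples - 1


def test_newick_export_contains_all_samples():
    expr, _, _, _ = _three_group_cohort(5)
    model = hcluster_signature(expr, tf_signature(), k=2)
    nwk = model.to_newick()
    assert nwk.endswith(";")
    for s in model.samples:
        assert s in nwk


def test_unanimous_anchor_labelling():
    expr, _, ann, truth = simulate_cohort(SimulationConfig(seed=5))
    model = hcluster_signature(expr, truth.signature, k=2)
    labelled = label_clusters(model, ann, "SMARCA4-UT")
    anchor_members = set(model.members_of(labelled.anchor_cluster))
    assert set(truth.smarca4_deficient) <= anchor_members
    assert (labelled.labels == "SMARCA4-UT").sum() == len(anchor_members)


def test_split_anchors_take_plurality_with_warning():
    expr, _, _, _ = _three_group_cohort(6)
    model = hcluster_signature(expr, tf_signature(), k=3)
    # anchors split evenly across two clusters: no strict majority
    c1 = model.members_of(1)[:3]
    c2 = model.members_of(2)[:3]
    ann = pd.DataFrame("SCLC", index=model.samples, columns=["reference_class"])
    ann.loc[c1 + c2, "reference_class"] = "SMARCA4-UT"
    with pytest.warns(UserWarning, match="plurality"):
        labelled = label_clusters(model, AnnotationTable(table=ann), "SMARCA4-UT")
    assert labelled.anchor_cluster == 1


def test_three_of_five_anchors_is_a_strict_majority():
    expr, _, _, _ = _three_group_cohort(6)
    model = hcluster_signature(expr, tf_signature(), k=3)
    c1 = model.members_of(1)[:3]
    c2 = model.members_of(2)[:2]
    ann = pd.DataFrame("SCLC", index=model.samples, columns=["reference_class"])
    ann.loc[c1 + c2, "reference_class"] = "SMARCA4-UT"
    labelled = label_clusters(model, AnnotationTable(table=ann), "SMARCA4-UT")
    assert labelled.anchor_cluster == 1


def test_anchor_class_absent_is_error():
    expr, _, ann, truth = simulate_cohort(SimulationConfig(seed=5))
    model = hcluster_signature(expr, truth.signature, k=2)
    with pytest.raises(ValidationError, match="no clustered sample"):
        label_clusters(model, ann, "NO-SUCH-CLASS")


def test_anchor_label_is_assigned_to_exactly_one_cluster():
    expr, _, ann, truth = simulate_cohort(SimulationConfig(seed=7))
    model = hcluster_signature(expr, truth.signature, k=4)
    labelled = label_clusters(model, ann, "SMARCA4-UT")
    anchor_clusters = set(
        model.assignment[labelled.labels == "SMARCA4-UT"].unique()
    )
    assert len(anchor_clusters) == 1


def test_null_batch_keeps_all_pcs_and_unions_top_genes():
    cfg = SimulationConfig(seed=2, batch_effect=0.0)
    expr, _, _, _ = simulate_cohort(cfg)
    report = batch_aware_gene_selection(expr, n_pcs=4, n_top=50)
    assert report.excluded == []
    assert report.retained == [1, 2, 3, 4]
    assert len(report.selected_genes) <= 200
    assert set(report.selected_genes) <= set(expr.gene_ids)


def test_planted_batch_pc_is_excluded_and_batch_genes_depleted():
    cfg = SimulationConfig(seed=11, batch_effect=5.0, batch_fraction=0.3)
    expr, _, _, truth = simulate_cohort(cfg)
    report = batch_aware_gene_selection(expr)
    assert len(report.excluded) == 1
    batch_genes = truth.batch_genes
    overall = len(batch_genes) / expr.n_genes
    selected_frac = len(set(report.selected_genes) & batch_genes) / len(
        report.selected_genes
    )
    assert selected_frac <= overall / 5


def test_manual_pc_exclusion_override():
    cfg = SimulationConfig(seed=2, batch_effect=0.0)
    expr, _, _, _ = simulate_cohort(cfg)
    report = batch_aware_gene_selection(expr, exclude_pcs=[2])
    assert report.excluded == [2]
    assert report.retained == [1, 3, 4]


def test_selection_improves_biology_ari_and_degrades_batch_ari():
    """Across seeds, clustering on selected genes tracks NE biology, not source."""
    wins = 0
    for seed in range(10):
        cfg = SimulationConfig(seed=seed, batch_effect=5.0)
        expr, _, _, truth = simulate_cohort(cfg)
        report = batch_aware_gene_selection(expr)
        bio = truth.true_subtype.map(lambda s: "NE" if s in ("A", "N") else "nonNE")
        all_sig = GeneSignature(name="all", members={g: "MEMBER" for g in expr.gene_ids})
        sel_sig = GeneSignature(
            name="sel", members={g: "MEMBER" for g in report.selected_genes}
        )
        m_all = hcluster_signature(expr, all_sig, k=2)
        m_sel = hcluster_signature(expr, sel_sig, k=2)
        ari_bio_all = adjusted_rand_score(bio.loc[m_all.samples], m_all.assignment)
        ari_bio_sel = adjusted_rand_score(bio.loc[m_sel.samples], m_sel.assignment)
        ari_bat_all = adjusted_rand_score(
            truth.true_batch.loc[m_all.samples], m_all.assignment
        )
        ari_bat_sel = adjusted_rand_score(
            truth.true_batch.loc[m_sel.samples], m_sel.assignment
        )
        wins += (ari_bio_sel > ari_bio_all) and (ari_bat_sel < ari_bat_all)
    assert wins >= 9
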