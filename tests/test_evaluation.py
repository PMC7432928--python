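import numpy as np
import pandas as pd
import pytest

from priddg import fixtures
from priddg.evaluate import (classification_metrics, cross_validate,
                             curate_dataset, max_mcc, regression_metrics,
                             rna_identity)


def test_perfect_prediction_metrics():
    x = np.array([0.1, 1.2, -0.5, 2.0, 0.7])
    r, rmse, slope = regression_metrics(x, x)
    assert (r, rmse, slope) == (pytest.approx(1.0), pytest.approx(0.0),
                                pytest.approx(1.0))


def test_anti_correlated_prediction():
    x = np.array([0.1, 1.2, -0.5, 2.0, 0.7])
    r, _, _ = regression_metrics(-x, x)
    assert r == pytest.approx(-1.0)


def test_regression_metrics_match_textbook_formulas():
    rng = np.random.default_rng(3)
    pred = rng.normal(size=50)
    exp = 0.8 * pred + rng.normal(scale=0.5, size=50)
    r, rmse, slope = regression_metrics(pred, exp)
    # hand-rolled formulas
    px, ex = pred - pred.mean(), exp - exp.mean()
    r_hand = float(np.sum(px * ex) / np.sqrt(np.sum(px**2) * np.sum(ex**2)))
    rmse_hand = float(np.sqrt(np.mean((pred - exp) ** 2)))
    slope_hand = float(np.sum(px * ex) / np.sum(px**2))
    assert r == pytest.approx(r_hand, abs=1e-10)
    assert rmse == pytest.approx(rmse_hand, abs=1e-10)
    assert slope == pytest.approx(slope_hand, abs=1e-10)


def test_zero_variance_rejected():
    with pytest.raises(ValueError, match="variance"):
        regression_metrics([1.0, 1.0, 1.0], [0.1, 0.2, 0.3])


def test_perfect_separation_classification():
    exp = np.array([2.0, 1.5, 1.2, 0.2, -0.5, 0.8])
    pred = exp.copy()
    auc_roc, auc_pr, mcc = classification_metrics(pred, exp)
    assert auc_roc == pytest.approx(1.0)
    assert auc_pr == pytest.approx(1.0)
    assert mcc == pytest.approx(1.0)


def test_max_mcc_of_clean_confusion_matrix():
    # TP=5, TN=5, FP=0, FN=0 at the best threshold
    labels = np.array([True] * 5 + [False] * 5)
    pred = np.array([2.0] * 5 + [-1.0] * 5)
    assert max_mcc(pred, labels) == pytest.approx(1.0)


def test_random_predictions_give_half_auc():
    rng = np.random.default_rng(12)
    exp = np.where(rng.random(4000) < 0.5, 2.0, 0.0)
    pred = rng.normal(size=4000)  # independent of labels
    auc_roc, _, _ = classification_metrics(pred, exp)
    assert auc_roc == pytest.approx(0.5, abs=0.05)


def test_single_class_labels_rejected():
    with pytest.raises(ValueError, match="both classes"):
        classification_metrics([0.1, 0.2, 0.3], [2.0, 3.0, 4.0])


def test_cv_splits_are_disjoint_and_deterministic():
    df = fixtures.make_synthetic_dataset(n_complexes=10, muts_per_complex=5,
                                         seed=5)
    out1 = cross_validate(df, "CV1", repeats=5, seed=42)
    out2 = cross_validate(df, "CV1", repeats=5, seed=42)
    assert out1["aggregate"].r == out2["aggregate"].r
    assert out1["aggregate"].rmse == out2["aggregate"].rmse
    for rep in out1["per_round"]:
        assert rep.n == 25  # 50/50 split of 50 mutations
    out_cv2 = cross_validate(df, "CV2", repeats=5, seed=42)
    for rep in out_cv2["per_round"]:
        assert rep.n == 10  # 20% of 50


def test_cv3_folds_partition_by_complex():
    df = fixtures.make_synthetic_dataset(n_complexes=10, muts_per_complex=5,
                                         seed=5)
    out = cross_validate(df, "CV3", seed=0)
    assert len(out["per_round"]) == 10
    assert sum(f["n_test"] for f in out["per_round"]) == len(df)
    assert np.isfinite(out["pooled_predictions"]).all()


def test_cv3_pooled_r_tracks_generative_model():
    true = fixtures.default_true_model(seed=5)
    df = fixtures.make_synthetic_dataset(true_model=true, n_complexes=50,
                                         muts_per_complex=5, noise_sd=0.76,
                                         seed=17)
    # generative R: correlation of the noiseless signal with the response
    signal = (true[0]
              + sum(true[1][k] * df[k] for k in true[1]))
    r_gen = float(np.corrcoef(signal, df["ddg_exp"])[0, 1])
    out = cross_validate(df, "CV3", seed=0)
    assert out["aggregate"].r == pytest.approx(r_gen, abs=0.1)


def test_cv3_needs_multiple_complexes():
    df = fixtures.make_synthetic_dataset(n_complexes=1, muts_per_complex=30,
                                         seed=1)
    with pytest.raises(ValueError, match="two complexes"):
        cross_validate(df, "CV3")


def _raw_table(**overrides):
    base = {
        "pdb_id": ["1AAA"] * 3,
        "protein_chain": ["A"] * 3,
        "position": [10, 11, 12],
        "wt_aa": ["T", "K", "S"],
        "mut_aa": ["A", "E", "A"],
        "ddg_exp": [0.5, 1.5, -0.2],
    }
    base.update(overrides)
    return pd.DataFrame(base)


def test_short_protein_rejected_at_boundary():
    raw = _raw_table(protein_length=[19, 20, 200])
    curated, report = curate_dataset(raw)
    assert len(curated) == 2
    assert any("protein length" in rule for _, rule in report)


def test_short_rna_rejected():
    raw = _raw_table(rna_length=[4, 5, 80])
    curated, report = curate_dataset(raw)
    assert len(curated) == 2
    assert any("RNA length" in rule for _, rule in report)


def test_metal_site_and_modified_interface_rejected():
    raw = _raw_table(metal_site=[True, False, False],
                     interface_modified=[False, True, False])
    curated, report = curate_dataset(raw)
    assert len(curated) == 1
    rules = [rule for _, rule in report]
    assert any("metal" in r for r in rules)
    assert any("modified" in r for r in rules)


def test_concordant_repeats_averaged_discordant_rejected():
    raw = pd.DataFrame({
        "pdb_id": ["1AAA"] * 3 + ["2BBB"] * 2,
        "protein_chain": ["A"] * 5,
        "position": [10] * 3 + [7] * 2,
        "wt_aa": ["T"] * 3 + ["K"] * 2,
        "mut_aa": ["A"] * 3 + ["E"] * 2,
        "ddg_exp": [0.5, 0.9, 0.7, 0.0, 2.0],
    })
    curated, report = curate_dataset(raw)
    assert len(curated) == 1
    assert curated.iloc[0]["ddg_exp"] == pytest.approx(0.7)
    assert any("averaged 3" in rule for _, rule in report)
    assert any("discordant" in rule for _, rule in report)


def test_rna_similarity_filter():
    seq_struct = "ACGUACGUAC"
    similar = "ACGUACGUGC"      # 90% identity
    dissimilar = "ACGUACGAGG"   # 70% identity
    assert rna_identity(seq_struct, similar) == pytest.approx(0.9)
    assert rna_identity(seq_struct, dissimilar) == pytest.approx(0.7)
    raw = _raw_table(
        rna_seq_structure=[seq_struct] * 3,
        rna_seq_assay=[similar, dissimilar, seq_struct],
    )
    curated, report = curate_dataset(raw)
    assert len(curated) == 2
    assert any("similarity" in rule for _, rule in report)


def test_malformed_rows_reported_not_fatal():
    raw = _raw_table(ddg_exp=[0.5, float("nan"), -0.2])
    curated, report = curate_dataset(raw)
    assert len(curated) == 2
    assert any("malformed" in rule for _, rule in report)
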