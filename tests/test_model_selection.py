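"""Grouped cross-validation, sparsity optimization and diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from smbpls import (
    ValidationError, align_blocks, confusion_and_success_rate, cross_validate,
    logo_splits, select_n_components, simulate_study,
)
from smbpls.model_selection import _subset_multiblock
from smbpls.model import encode_classes
from smbpls.preprocess import preprocess_blocks

from conftest import make_table, multiblock_from_arrays, small_sim_config


# --------------------------------------------------------------------------
# fold construction
# --------------------------------------------------------------------------

def _meta(subjects):
    return pd.DataFrame({"subject_id": subjects})


def test_logo_one_fold_per_subject_all_time_points_together():
    folds = logo_splits(_meta(["p1", "p1", "p2", "p2", "p3", "p3"]))
    assert len(folds) == 3
    for train, test in folds:
        assert len(test) == 2
        assert set(train) | set(test) == set(range(6))
        assert not set(train) & set(test)


def test_logo_thirty_subjects_thirty_folds():
    subjects = [f"p{i:02d}" for i in range(30) for _ in range(3)]
    assert len(logo_splits(_meta(subjects))) == 30


def test_logo_singleton_subject_allowed():
    folds = logo_splits(_meta(["p1", "p1", "p2"]))
    sizes = sorted(len(test) for _, test in folds)
    assert sizes == [1, 2]


def test_logo_single_subject_errors():
    with pytest.raises(ValidationError, match="subject"):
        logo_splits(_meta(["p1", "p1"]))


# --------------------------------------------------------------------------
# component-count selection
# --------------------------------------------------------------------------

def test_one_se_rule_example():
    mcr = np.array([0.40, 0.20, 0.19, 0.25])
    # two folds at the argmin with SE exactly 0.02
    folds = np.array([
        [0.40, 0.40], [0.20, 0.20], [0.19 - 0.02, 0.19 + 0.02], [0.25, 0.25],
    ])
    assert select_n_components(mcr, folds) == 2  # 0.20 <= 0.19 + 0.02


def test_strictly_decreasing_mcr_zero_se_selects_max():
    mcr = np.array([0.4, 0.3, 0.2, 0.1])
    folds = np.tile(mcr[:, None], (1, 5))
    assert select_n_components(mcr, folds) == 4


def test_flat_mcr_selects_one_component():
    mcr = np.array([0.3, 0.3, 0.3])
    folds = np.tile(mcr[:, None], (1, 4))
    assert select_n_components(mcr, folds) == 1


def test_mcnemar_rule_agrees_on_identical_predictions():
    mcr = np.array([0.5, 0.0])
    folds = np.tile(mcr[:, None], (1, 4))
    truth = ["A", "B"] * 10
    preds = [["A"] * 20, list(truth)]
    a = select_n_components(
        mcr, folds, rule="mcnemar", predictions_per_a=preds, true_labels=truth
    )
    assert a == 2  # model 1 is significantly worse


# --------------------------------------------------------------------------
# confusion matrix and success rate
# --------------------------------------------------------------------------

def test_confusion_pooled_counts_and_success_rate():
    true = ["A"] * 6 + ["B"] * 6
    pred = ["A"] * 5 + ["B"] + ["A"] * 2 + ["B"] * 4
    mat, sr, sens = confusion_and_success_rate(true, pred)
    assert mat.loc["A", "A"] == 5 and mat.loc["A", "B"] == 1
    assert mat.loc["B", "A"] == 2 and mat.loc["B", "B"] == 4
    assert sr == pytest.approx(9 / 12)
    assert list(mat.sum(axis=1)) == [6, 6]  # row sums = true class counts


def test_confusion_perfect_prediction():
    true = ["x", "y", "x"]
    _, sr, sens = confusion_and_success_rate(true, true)
    assert sr == 1.0
    assert sens == {"x": 1.0, "y": 1.0}


def test_confusion_all_one_class_predicted():
    true = ["x", "y"]
    _, sr, sens = confusion_and_success_rate(true, ["x", "x"])
    assert sens["x"] == 1.0 and sens["y"] == 0.0


def test_confusion_label_outside_class_set_errors():
    with pytest.raises(ValidationError, match="outside"):
        confusion_and_success_rate(["A"], ["C"], class_labels=["A", "B"])


# --------------------------------------------------------------------------
# cross-validation behavior
# --------------------------------------------------------------------------

def _separable_multiblock(n_subjects=6, noise=0.05, seed=4):
    rng = np.random.default_rng(seed)
    n = n_subjects * 2
    labels = ["A"] * n_subjects + ["B"] * n_subjects
    subjects = [f"p{i:02d}" for i in range(n_subjects) for _ in (0, 1)]
    subjects = [f"p{i:02d}" for i in range(n)]  # one sample per subject here
    X = np.where(np.array(labels)[:, None] == "A", -1.0, 1.0) * np.ones((n, 5))
    X = X + rng.normal(scale=noise, size=X.shape) + 10.0
    return multiblock_from_arrays([X], labels=labels, subjects=subjects), labels


def test_cv_perfectly_separable_toy_is_perfect():
    mb, labels = _separable_multiblock()
    res = cross_validate(mb, labels, grid=(0.0,), a_max=1)
    assert res.sr_cv == 1.0
    assert res.mcr == 0.0
    mat = res.confusion.to_numpy()
    assert np.all(mat == np.diag(np.diag(mat)))


def test_cv_grid_zero_gives_dense_path():
    mb, labels = _separable_multiblock()
    res = cross_validate(mb, labels, grid=(0.0,), a_max=2)
    assert res.g_path == [0.0, 0.0]


def test_cv_tied_error_prefers_smaller_degree():
    mb, labels = _separable_multiblock()   # every g classifies perfectly
    res = cross_validate(mb, labels, grid=(0.0, 0.5, 0.9), a_max=1)
    assert res.g_path == [0.0]


def test_cv_empty_grid_errors():
    mb, labels = _separable_multiblock()
    with pytest.raises(ValidationError, match="grid"):
        cross_validate(mb, labels, grid=(), a_max=1)


def test_cv_is_deterministic():
    tables, _, _, truth = simulate_study(small_sim_config(seed=9))
    mb = align_blocks(tables)
    labels = [truth.class_labels[s] for s in mb.sample_ids]
    r1 = cross_validate(mb, labels, grid=(0.0, 0.9), a_max=1)
    r2 = cross_validate(mb, labels, grid=(0.0, 0.9), a_max=1)
    assert r1.predictions == r2.predictions
    assert np.array_equal(r1.mcr_surface, r2.mcr_surface)


def test_cv_null_data_success_rate_near_chance():
    # shuffled labels on signal-free data: SR_CV should fall in the central
    # 95% binomial band around 1/2
    cfg = small_sim_config(
        seed=7, n_subjects_per_diet=10,
        block_kwargs=dict(effect_size_logsd=0.0, time_effect_logsd=0.0,
                          missing_sample_rate=0.0),
    )
    tables, _, _, truth = simulate_study(cfg)
    mb = align_blocks(tables)
    rng = np.random.default_rng(7)
    labels = rng.permutation([truth.class_labels[s] for s in mb.sample_ids]).tolist()
    res = cross_validate(mb, labels, grid=(0.9,), a_max=1)
    n = mb.n_samples
    lo = sps.binom.ppf(0.025, n, 0.5) / n
    hi = sps.binom.ppf(0.975, n, 0.5) / n
    assert lo <= res.sr_cv <= hi


def test_cv_regression_mode_reports_rmse():
    rng = np.random.default_rng(12)
    n = 16
    subjects = [f"p{i}" for i in range(n)]
    y = rng.normal(size=n)
    X = np.outer(y, np.ones(4)) + rng.normal(scale=0.1, size=(n, 4))
    mb = multiblock_from_arrays([X], subjects=subjects)
    res = cross_validate(mb, y, grid=(0.0,), a_max=1, mode="regression")
    assert res.rmse is not None and res.rmse < np.std(y)


def test_three_class_weak_middle_has_lowest_sensitivity():
    # time classification: planted monotone trends make the middle week
    # the hardest class, echoing the weak mid-study metabotype
    cfg = small_sim_config(
        seed=3, n_subjects_per_diet=8,
        block_kwargs=dict(effect_size_logsd=0.0, time_effect_logsd=0.8,
                          n_time_markers=10, missing_sample_rate=0.0),
    )
    tables, _, _, truth = simulate_study(cfg)
    mb = align_blocks(tables)
    weeks = mb.sample_meta["time_point"].tolist()
    res = cross_validate(mb, weeks, grid=(0.9,), a_max=2)
    sens = res.sensitivities
    assert sens["week12"] == min(sens.values())


# --------------------------------------------------------------------------
# leakage
# --------------------------------------------------------------------------

def test_training_preprocessing_ignores_test_subject():
    # corrupting a held-out subject's intensities must leave the training
    # scaling state and fitted model of that fold bit-identical
    tables, _, _, truth = simulate_study(small_sim_config(seed=21))
    mb = align_blocks(tables)
    labels = [truth.class_labels[s] for s in mb.sample_ids]
    subjects = mb.sample_meta["subject_id"].to_numpy()
    target = sorted(set(subjects))[0]
    test_idx = np.nonzero(subjects == target)[0]
    train_idx = np.nonzero(subjects != target)[0]

    corrupted = mb.map_blocks(
        lambda arr, i: np.where(
            np.isin(np.arange(arr.shape[0]), test_idx)[:, None], arr * 1e3, arr
        )
    )

    from smbpls.model import fit_smbplsr
    enc = encode_classes(labels)

    def fold_fit(blocks):
        tr = _subset_multiblock(blocks, train_idx)
        pre, state = preprocess_blocks(tr)
        model = fit_smbplsr(
            pre, encode_classes([labels[i] for i in train_idx]), A=1,
            sparsity_degrees=0.9, scaling_state=state,
        )
        return state, model

    state_a, model_a = fold_fit(mb)
    state_b, model_b = fold_fit(corrupted)
    for ca, cb in zip(state_a.columns, state_b.columns):
        assert np.array_equal(ca.means, cb.means)
        assert np.array_equal(ca.divisors, cb.divisors)
    assert state_a.frobenius_norms == state_b.frobenius_norms
    assert np.array_equal(model_a.W, model_b.W)
    assert np.array_equal(model_a.B, model_b.B)


def test_sparse_signal_drives_degree_of_sparsity_upward():
    """With a strong signal in 10 of 500 features, the greedy search picks
    a clearly sparse first component and sparse models beat dense ones."""
    from smbpls import MultiBlock
    from smbpls.model_selection import DEFAULT_SPARSITY_GRID
    from smbpls.simulate import BlockSimConfig, SimConfig

    sparse_chosen = 0
    sparse_beats_dense = 0
    for rep in range(5):
        cfg = SimConfig(
            blocks=(BlockSimConfig(
                name="plasma", n_features=500, n_diet_markers=10,
                n_time_markers=0, effect_size_logsd=1.5,
                missing_sample_rate=0.0,
            ),),
            seed=3000 + rep,
        )
        tables, _, _, truth = simulate_study(cfg)
        mb = MultiBlock([tables[0].rows_with_role("sample")])
        labels = [truth.class_labels[s] for s in mb.sample_ids]
        res = cross_validate(mb, labels, grid=DEFAULT_SPARSITY_GRID, a_max=1)
        sparse_chosen += res.g_path[0] >= 0.8
        row = res.mcr_surface[0]
        sparse_beats_dense += row[1:].min() < row[0]
    assert sparse_chosen >= 4
    assert sparse_beats_dense >= 4
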