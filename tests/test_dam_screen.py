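import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import comb
from sklearn.metrics import silhouette_score

from hausflow.dam_screen import (
    coregulation_classes,
    DamRecord,
    fit_opls_da,
    hypergeometric_enrichment,
    log2_fold_change,
    pca_qc,
    screen_dams,
    vip_scores,
)

from conftest import make_table


# -- fold change ------------------------------------------------------------


def test_log2fc_doubling_is_one():
    assert log2_fold_change(100, 200, 1e-12) == pytest.approx(1.0)


@given(x=st.floats(0, 1e9, allow_nan=False), pseudo=st.floats(1e-6, 1e3))
@settings(max_examples=50, deadline=None)
def test_log2fc_identity(x, pseudo):
    assert log2_fold_change(x, x, pseudo) == 0.0


def test_log2fc_zero_reference_with_pseudo():
    assert log2_fold_change(0, 800, 1.0) == pytest.approx(math.log2(801), abs=1e-12)


def test_log2fc_negative_input_is_error():
    with pytest.raises(ValueError):
        log2_fold_change(-1, 5, 1.0)
    with pytest.raises(ValueError):
        log2_fold_change(1, 5, 0.0)


# -- OPLS-DA ----------------------------------------------------------------


def two_class_y(n_per_class):
    return np.array([-1.0] * n_per_class + [1.0] * n_per_class)


def test_single_perfect_feature_reproduces_labels():
    X = np.array([[1.0, 1.0, 1.0, 3.0, 3.0, 3.0]])  # features x samples
    y = two_class_y(3)
    model = fit_opls_da(X, y, n_orthogonal=0)
    assert model.r2y == pytest.approx(1.0)
    scaled = model.scores / np.linalg.norm(model.scores)
    assert np.allclose(scaled, y / np.linalg.norm(y))


def test_pure_noise_feature_gets_negligible_weight():
    rng = np.random.default_rng(3)
    n = 6
    y = two_class_y(3)
    informative = np.vstack([y * 10 * (1 + rng.normal(0, 0.01, n)) for _ in range(10)])
    noise = rng.normal(0, 1, size=(1, n))
    X = np.vstack([informative, noise])
    model = fit_opls_da(X, y, n_orthogonal=0)
    assert abs(model.weights[-1]) < 0.1


def test_sample_permutation_equivariance():
    rng = np.random.default_rng(7)
    X = rng.lognormal(1, 1, size=(12, 8))
    y = np.array([-1.0] * 4 + [1.0] * 4)
    model = fit_opls_da(X, y, n_orthogonal=1)
    perm = rng.permutation(8)
    model_p = fit_opls_da(X[:, perm], y[perm], n_orthogonal=1)
    assert np.allclose(model_p.scores, model.scores[perm])


def test_predictive_scores_orthogonal_to_orthogonal_scores():
    rng = np.random.default_rng(11)
    X = rng.lognormal(2, 1, size=(30, 10))
    y = np.array([-1.0] * 5 + [1.0] * 5)
    model = fit_opls_da(X, y, n_orthogonal=2)
    for to in model.orthogonal_scores:
        assert abs(model.scores @ to) <= 1e-8 * np.linalg.norm(model.scores) * np.linalg.norm(to)


def test_zero_variance_feature_excluded_with_warning():
    X = np.array([[1.0, 1, 1, 3, 3, 3], [2.0, 2, 2, 2, 2, 2]])
    with pytest.warns(UserWarning, match="zero-variance"):
        model = fit_opls_da(X, two_class_y(3), n_orthogonal=0)
    assert model.excluded_features == ["f1"]
    assert model.feature_ids == ["f0"]


def test_too_many_orthogonal_components_is_error():
    X = np.random.default_rng(0).normal(size=(3, 6))
    with pytest.raises(ValueError, match="n_orthogonal"):
        fit_opls_da(X, two_class_y(3), n_orthogonal=5)


# -- VIP --------------------------------------------------------------------


def test_identical_features_all_vip_one():
    base = np.array([1.0, 1.2, 0.9, 3.0, 3.3, 2.8])
    X = np.vstack([base] * 7)
    model = fit_opls_da(X, two_class_y(3), n_orthogonal=0)
    vips = vip_scores(model)
    assert all(v == pytest.approx(1.0, abs=1e-10) for v in vips.values())


@pytest.mark.parametrize("n_orthogonal", [0, 1, 2])
def test_mean_squared_vip_is_one(n_orthogonal):
    rng = np.random.default_rng(13 + n_orthogonal)
    X = rng.lognormal(0, 1, size=(25, 12))
    y = np.array([-1.0] * 6 + [1.0] * 6)
    vips = np.array(list(vip_scores(fit_opls_da(X, y, n_orthogonal)).values()))
    assert np.mean(vips**2) == pytest.approx(1.0, abs=1e-8)


def test_vip_matches_independent_oracle():
    # textbook formula recomputed from scratch on a fixed-seed 6 x 10 matrix:
    # UV-scale X, w ∝ X'y (unit norm), t = Xw, q = y't/t't,
    # SSY_1 = q^2 t't, VIP_j = sqrt(p * SSY_1 w_j^2 / SSY_1)
    rng = np.random.default_rng(99)
    X = rng.lognormal(1, 0.8, size=(10, 6))  # features x samples
    y = two_class_y(3)

    M = X.T
    Z = (M - M.mean(axis=0)) / M.std(axis=0, ddof=1)
    yc = y - y.mean()
    w = Z.T @ yc
    w = w / np.linalg.norm(w)
    expected = np.sqrt(10 * w**2)

    vips = vip_scores(fit_opls_da(X, y, n_orthogonal=0))
    assert np.allclose(list(vips.values()), expected, atol=1e-8)


# -- DAM calls --------------------------------------------------------------


def test_dam_rule_boundaries():
    rec = DamRecord("m", ("TH", "THC"), 1.5, 1.2, "up")
    assert rec.regulation == "up"
    # rule checks happen in screen_dams; verify via a constructed table
    rng = np.random.default_rng(2)
    base = np.full((3, 6), 100.0) * (1 + rng.normal(0, 0.001, (3, 6)))
    base[0, 3:] *= 4.0  # clear up
    table = make_table(base, n_reps=3, compartments=("TH", "THC"), kind="metabolite")
    recs = {r.feature_id: r for r in screen_dams(table, ("TH", "THC"))}
    assert recs["f0"].regulation == "up"
    assert recs["f1"].regulation == "not_significant"


def test_high_fc_low_vip_is_not_significant():
    # 50 strong discriminating features dilute a weak-VIP one: feature f50
    # has a 4-fold mean shift but huge within-class spread
    rng = np.random.default_rng(4)
    strong = np.vstack(
        [np.concatenate([np.full(3, 10.0), np.full(3, 40.0)]) * (1 + rng.normal(0, 0.01, 6)) for _ in range(50)]
    )
    weak = np.array([[1.0, 350.0, 60.0, 30.0, 380.0, 90.0]])
    table = make_table(np.vstack([strong, weak]), n_reps=3, compartments=("TH", "THC"))
    recs = {r.feature_id: r for r in screen_dams(table, ("TH", "THC"))}
    assert recs["f50"].vip < 1
    assert recs["f50"].regulation == "not_significant"


def test_screen_recovers_planted_features_exactly():
    rng = np.random.default_rng(17)
    n, planted = 1000, 20
    means = np.exp(rng.normal(5, 1, size=n))
    mat = np.empty((n, 6))
    mat[:, :3] = means[:, None]
    mat[:, 3:] = means[:, None]
    mat[:planted, 3:] *= 4.0
    mat *= np.exp(0.05 * rng.normal(size=mat.shape) - 0.05**2 / 2)
    table = make_table(mat, n_reps=3, compartments=("TH", "THC"), kind="metabolite")
    ups = {r.feature_id for r in screen_dams(table, ("TH", "THC")) if r.regulation == "up"}
    assert ups == {f"f{i}" for i in range(planted)}


def test_screen_invariant_to_feature_and_sample_order():
    rng = np.random.default_rng(23)
    mat = rng.lognormal(3, 1, size=(40, 6))
    table = make_table(mat, n_reps=3, compartments=("TH", "THC"))
    base = {r.feature_id: (r.log2fc, r.vip, r.regulation) for r in screen_dams(table, ("TH", "THC"))}

    fids = [table.feature_ids[i] for i in rng.permutation(40)]
    sids = [table.sample_ids[i] for i in (0, 2, 1, 5, 3, 4)]  # within compartments
    table2 = table.subset_features(fids).subset_samples(sids)
    got = {r.feature_id: (r.log2fc, r.vip, r.regulation) for r in screen_dams(table2, ("TH", "THC"))}
    for fid in base:
        assert got[fid][2] == base[fid][2]
        assert got[fid][0] == pytest.approx(base[fid][0])
        assert got[fid][1] == pytest.approx(base[fid][1])


def test_dam_call_monotone_in_effect_size():
    rng = np.random.default_rng(31)
    noise = rng.normal(size=(50, 6))  # frozen: only the planted effect varies
    calls = []
    for fc in (2.0, 3.0, 4.0, 8.0, 16.0):
        mat = np.full((50, 6), 50.0)
        mat[0, 3:] *= fc
        mat *= np.exp(0.05 * noise - 0.05**2 / 2)
        table = make_table(mat, n_reps=3, compartments=("TH", "THC"))
        rec = next(r for r in screen_dams(table, ("TH", "THC")) if r.feature_id == "f0")
        calls.append(rec.regulation)
    assert calls[-1] == "up"
    first_up = calls.index("up")
    assert all(c == "up" for c in calls[first_up:])  # never flips back


# -- co-regulation ----------------------------------------------------------


def dam(fid, reg, comp=("TH", "THC")):
    return DamRecord(fid, comp, 2.0 if reg == "up" else -2.0, 1.5, reg)


def test_coregulation_type_pairs():
    a = [dam("jasmonic", "up"), dam("tartaric", "up"), dam("only_a", "up")]
    b = [dam("jasmonic", "up", ("P", "PC")), dam("tartaric", "down", ("P", "PC"))]
    recs = {r.feature_id: r.type_pair for r in coregulation_classes(a, b)}
    assert recs == {"jasmonic": ("up", "up"), "tartaric": ("up", "down")}


def test_coregulation_disjoint_sets_empty():
    assert coregulation_classes([dam("a", "up")], [dam("b", "down", ("P", "PC"))]) == []


def test_coregulation_excludes_not_significant():
    a = [dam("x", "up"), DamRecord("y", ("TH", "THC"), 0.2, 0.5, "not_significant")]
    b = [dam("x", "up", ("P", "PC")), dam("y", "up", ("P", "PC"))]
    assert [r.feature_id for r in coregulation_classes(a, b)] == ["x"]


# -- PCA QC -----------------------------------------------------------------


def test_pca_separates_compartment_clusters(experiment):
    gene_table = experiment[0]
    res = pca_qc(gene_table, n_components=2)
    labels = [gene_table.sample_to_compartment[s] for s in res.sample_ids]
    assert silhouette_score(res.scores[:, :2], labels) > 0.5


def test_pca_duplicated_sample_identical_scores():
    rng = np.random.default_rng(8)
    mat = rng.lognormal(0, 1, size=(30, 8))
    mat[:, 3] = mat[:, 2]  # duplicate a sample
    table = make_table(mat, n_reps=2)
    res = pca_qc(table)
    assert np.allclose(res.scores[3], res.scores[2])


def test_pca_single_feature_explains_everything():
    table = make_table(np.array([[1.0, 5.0, 9.0, 2.0]]), n_reps=1)
    res = pca_qc(table)
    assert res.explained_variance_ratio[0] == pytest.approx(1.0)


def test_pca_sign_convention_deterministic():
    rng = np.random.default_rng(9)
    mat = rng.lognormal(0, 1, size=(12, 8))
    table = make_table(mat, n_reps=2)
    res = pca_qc(table)
    for comp in res.loadings.T:
        assert comp[np.argmax(np.abs(comp))] > 0


# -- enrichment -------------------------------------------------------------


def test_hypergeometric_all_selected_in_term():
    universe = [f"m{i}" for i in range(10)]
    selected = universe[:5]
    recs = hypergeometric_enrichment(selected, universe, {"T": universe[:5]})
    assert recs[0].p_value == pytest.approx(1 / comb(10, 5), rel=1e-12)


def test_hypergeometric_k_zero_p_one():
    universe = [f"m{i}" for i in range(10)]
    recs = hypergeometric_enrichment(universe[5:], universe, {"T": universe[:5]})
    # k can be 0 when the term and selection are disjoint; upper tail at 0 is 1
    assert recs[0].n_term_selected == 0
    assert recs[0].p_value == pytest.approx(1.0)


def test_hypergeometric_saturated_selection():
    universe = [f"m{i}" for i in range(8)]
    recs = hypergeometric_enrichment(universe, universe, {"A": universe[:3], "B": universe[5:]})
    assert all(r.p_value == pytest.approx(1.0) for r in recs)


def test_hypergeometric_empty_term_flagged():
    recs = hypergeometric_enrichment(["a"], ["a", "b"], {"T": ["zzz"]})
    assert recs[0].empty_term and recs[0].p_value == 1.0


def test_hypergeometric_selected_outside_universe_is_error():
    with pytest.raises(ValueError):
        hypergeometric_enrichment(["x"], ["a"], {})
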