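import numpy as np
import pytest
from scipy import stats

from hausflow.haustoria_network import (
    common_chimera_genes,
    pearson_network,
    select_haustoria_genes,
)
from hausflow.synthetic_data import SimParams, generate_experiment

from conftest import make_table


# -- common gene sets -------------------------------------------------------


def test_intersection_basic():
    assert common_chimera_genes({"a", "b", "c"}, {"b", "c", "d"}) == ["b", "c"]


def test_intersection_disjoint():
    assert common_chimera_genes({"a"}, {"b"}) == []


def test_intersection_recovers_planted_shared_genes():
    rng = np.random.default_rng(41)
    shared = {f"s{i}" for i in range(30)}
    thc = shared | {f"t{i}" for i in range(50)}
    pc = shared | {f"p{i}" for i in range(40)}
    assert set(common_chimera_genes(thc, pc)) == shared
    assert common_chimera_genes(thc, pc) == sorted(shared)


# -- haustoria gene selection ----------------------------------------------


def replicate_table(mean_rows, feature_ids, cv=0.03, seed=0):
    """Expand per-compartment means into 3 noisy replicates each."""
    rng = np.random.default_rng(seed)
    means = np.asarray(mean_rows, dtype=float)
    mat = np.repeat(means, 3, axis=1)
    mat = mat * np.exp(cv * rng.normal(size=mat.shape) - cv**2 / 2)
    return make_table(mat, feature_ids=feature_ids, n_reps=3, kind="gene")


def test_low_intact_host_expression_satisfies_any_mode():
    # chimera-induced actin-like profile: TH 0.3, THC 5.2, PC 1.7, P 0.0 plus
    # a background gene to absorb the BH correction
    table = replicate_table(
        [[0.3, 5.2, 1.7, 0.001], [100.0, 102.0, 99.0, 101.0]], ["act11", "bg"]
    )
    call = {c.feature_id: c for c in select_haustoria_genes(table, intact_mode="any")}["act11"]
    assert call.intact_min_fpkm < 0.3
    assert call.upregulated_thc and call.upregulated_pc
    assert call.qualifies
    both = {c.feature_id: c for c in select_haustoria_genes(table, intact_mode="both")}["act11"]
    assert not both.qualifies  # TH = 0.3 fails the max-based predicate


def test_gene_high_in_both_intact_roots_never_qualifies():
    table = replicate_table(
        [[50.0, 500.0, 500.0, 50.0], [100.0, 102.0, 99.0, 101.0]], ["g", "bg"]
    )
    for mode in ("any", "both"):
        call = {c.feature_id: c for c in select_haustoria_genes(table, intact_mode=mode)}["g"]
        assert call.upregulated_thc and call.upregulated_pc
        assert not call.qualifies


def test_planted_haustoria_genes_recovered_exactly(experiment):
    genes, _, _, _, truth = experiment
    selected = {c.feature_id for c in select_haustoria_genes(genes) if c.qualifies}
    assert selected == truth.haustoria_genes


def test_candidate_ids_restrict_output():
    table = replicate_table([[0.1, 50.0, 50.0, 0.1], [0.1, 50.0, 50.0, 0.1]], ["a", "b"])
    calls = select_haustoria_genes(table, candidate_ids=["b"])
    assert [c.feature_id for c in calls] == ["b"]


def test_unknown_intact_mode_is_error():
    table = replicate_table([[1.0, 2.0, 3.0, 4.0]], ["g"])
    with pytest.raises(ValueError):
        select_haustoria_genes(table, intact_mode="either")


# -- Pearson network --------------------------------------------------------


def chimera_pair_tables(gene_vec, metab_vec):
    """Two 1-feature tables over the 6 chimera samples (+ intact padding)."""
    pad = [1.0, 1.0, 1.0]
    gmat = [pad + list(gene_vec[:3]) + list(gene_vec[3:]) + pad]
    mmat = [pad + list(metab_vec[:3]) + list(metab_vec[3:]) + pad]
    g = make_table(gmat, feature_ids=["g"], n_reps=3, kind="gene")
    m = make_table(mmat, feature_ids=["m"], n_reps=3, kind="metabolite")
    return g, m


def test_exact_linear_relation_retained_with_smallest_p():
    x = np.array([1.0, 2, 3, 4, 5, 6])
    g, m = chimera_pair_tables(2 * x, x)
    edges = pearson_network(g, m)
    assert len(edges) == 1
    assert edges[0].pcc == pytest.approx(1.0)
    assert edges[0].sign == "pos"
    assert 0 < edges[0].p_value <= np.nextafter(0.0, 1.0)


def test_boundary_pcc_excluded_strictly():
    rng = np.random.default_rng(47)
    x = rng.normal(size=6)
    y = rng.normal(size=6)
    g, m = chimera_pair_tables(np.abs(x) + 5, np.abs(y) + 5)
    gv = g.frame.iloc[0, 3:9].to_numpy()
    mv = m.frame.iloc[0, 3:9].to_numpy()
    r = abs(float(np.corrcoef(gv, mv)[0, 1]))
    # pcc_min equal to the achieved |r|: strict > must exclude the edge
    assert pearson_network(g, m, pcc_min=r, p_max=1.1) == []
    assert len(pearson_network(g, m, pcc_min=r * 0.999, p_max=1.1)) == 1


def test_constant_vector_warns_and_skips():
    g, m = chimera_pair_tables(np.ones(6), np.arange(6.0) + 1)
    with pytest.warns(UserWarning, match="constant"):
        assert pearson_network(g, m, pcc_min=0.1, p_max=1.1) == []


def test_fewer_than_three_samples_is_error():
    g, m = chimera_pair_tables(np.arange(6.0) + 1, np.arange(6.0) + 1)
    with pytest.raises(ValueError, match=">= 3"):
        pearson_network(g, m, samples=["THC_1", "THC_2"])


def test_edges_invariant_under_joint_sample_permutation():
    rng = np.random.default_rng(53)
    g, m = chimera_pair_tables(rng.lognormal(0, 1, 6), rng.lognormal(0, 1, 6))
    samples = ["THC_1", "THC_2", "THC_3", "PC_1", "PC_2", "PC_3"]
    perm = [samples[i] for i in rng.permutation(6)]
    e1 = pearson_network(g, m, samples=samples, pcc_min=0.0, p_max=1.1)
    e2 = pearson_network(g, m, samples=perm, pcc_min=0.0, p_max=1.1)
    assert e1[0].pcc == pytest.approx(e2[0].pcc)
    assert e1[0].p_value == pytest.approx(e2[0].p_value)


def test_affine_invariance_of_correlation():
    rng = np.random.default_rng(59)
    for trial in range(5):
        x = rng.lognormal(0, 1, 6)
        y = rng.lognormal(0, 1, 6)
        a, b = rng.uniform(0.5, 3), rng.uniform(0, 10)
        g1, m1 = chimera_pair_tables(x, y)
        g2, m2 = chimera_pair_tables(x, a * y + b)
        e1 = pearson_network(g1, m1, pcc_min=0.0, p_max=1.1)[0]
        e2 = pearson_network(g2, m2, pcc_min=0.0, p_max=1.1)[0]
        assert e2.pcc == pytest.approx(e1.pcc, abs=1e-10)
        assert e2.sign == e1.sign


def test_t_transform_p_matches_fresh_draw_monte_carlo_null():
    # calibration check of the p-value transform: for independent normal
    # vectors the t-based p is exact, so an unconditional simulation null
    # must agree within Monte-Carlo error
    rng = np.random.default_rng(61)
    n, n_sim = 6, 200_000
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    r_obs = float(np.corrcoef(x, y)[0, 1])
    t = abs(r_obs) * np.sqrt((n - 2) / (1 - r_obs**2))
    p_t = 2 * stats.t.sf(t, df=n - 2)

    sims_x = rng.normal(size=(n_sim, n))
    sims_y = rng.normal(size=(n_sim, n))
    sx = (sims_x - sims_x.mean(1, keepdims=True))
    sy = (sims_y - sims_y.mean(1, keepdims=True))
    r_null = (sx * sy).sum(1) / np.sqrt((sx**2).sum(1) * (sy**2).sum(1))
    p_mc = float(np.mean(np.abs(r_null) >= abs(r_obs)))
    se = np.sqrt(p_mc * (1 - p_mc) / n_sim)
    assert abs(p_t - p_mc) <= 3 * se


def test_planted_pairs_recovered_at_least_95_percent():
    # scaled-down version of the 100-replicate property (30 seeds here; the
    # acceptance pipeline exercises the full-size experiment)
    base = dict(n_genes=40, n_metabolites=40, n_mobile_th_to_p=0, n_mobile_p_to_th=0,
                n_transferred_host_to_parasite=0, n_transferred_parasite_to_host=0,
                n_haustoria_genes=0, n_common_dams=0, n_correlated_pairs=8,
                genome_length=5000, unigene_length=(200, 400))
    hits = total = false_edges = pairs_tested = 0
    for seed in range(30):
        genes, metabs, _, _, truth = generate_experiment(SimParams(**base, seed=seed))
        pg = sorted({t[0] for t in truth.correlated_pairs})
        pm = sorted({t[1] for t in truth.correlated_pairs})
        edges = pearson_network(genes.subset_features(pg), metabs.subset_features(pm))
        got = {(e.gene_id, e.metabolite_id) for e in edges}
        want = {(a, b) for a, b, _ in truth.correlated_pairs}
        hits += len(got & want)
        total += len(want)
        false_edges += len(got - want)
        pairs_tested += len(pg) * len(pm) - len(want)
    assert hits / total >= 0.95
    # false edges consistent with the p < 0.05 threshold under independence
    false_rate = false_edges / pairs_tested
    se = np.sqrt(0.05 * 0.95 / pairs_tested)
    assert false_rate < 0.05 + 4 * se
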