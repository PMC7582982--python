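"""ER null ensembles, Z-scores, significance profiles and RD-scores."""

import numpy as np
import pytest

import motifsync as ms


def _summary(means, stds, n=500):
    return ms.EnsembleSummary(np.asarray(means, float),
                              np.asarray(stds, float), n, "manual", 0)


def test_saturated_ensemble_is_deterministic(cat3):
    # n=3, m=6: the only simple digraph is the 3-clique
    ens = ms.er_ensemble(3, 6, 50, cat3, seed=1)
    idx = cat3.index_of_name("clique")
    assert ens.means[idx] == 1.0 and ens.stds[idx] == 0.0
    others = np.delete(np.arange(13), idx)
    assert np.all(ens.means[others] == 0.0)


def test_empty_ensemble_all_zero(cat3):
    ens = ms.er_ensemble(10, 0, 20, cat3, seed=2)
    assert np.all(ens.means == 0.0) and np.all(ens.stds == 0.0)


def test_ensemble_reproducible_bit_exact(cat3):
    a = ms.er_ensemble(20, 60, 60, cat3, seed=3)
    b = ms.er_ensemble(20, 60, 60, cat3, seed=3)
    assert np.array_equal(a.means, b.means)
    assert np.array_equal(a.raw_counts, b.raw_counts)


def test_z_score_definition_and_normalization(cat3):
    counts = np.zeros(13, dtype=int)
    counts[0], counts[1] = 13, 14
    real = ms.CensusVector("x", 3, counts)
    means = np.zeros(13); stds = np.zeros(13)
    means[0], stds[0] = 10.0, 1.0     # Z = 3
    means[1], stds[1] = 10.0, 1.0     # Z = 4
    prof = ms.z_scores(real, _summary(means, stds))
    assert prof.z[0] == 3.0 and prof.z[1] == 4.0
    assert prof.sp[0] == pytest.approx(0.6) and prof.sp[1] == pytest.approx(0.8)
    # sigma = 0 entries are undefined and excluded from the norm
    assert prof.undefined[2:].all()
    assert np.isnan(prof.z[2])
    defined = prof.sp[~prof.undefined]
    assert np.linalg.norm(defined) == pytest.approx(1.0)


def test_z_zero_when_real_equals_mean(cat3):
    counts = np.full(13, 5)
    prof = ms.z_scores(ms.CensusVector("x", 3, counts),
                       _summary(np.full(13, 5.0), np.full(13, 2.0)))
    assert np.all(prof.z == 0.0)
    assert not prof.any_undefined


def test_rd_score_worked_cases():
    counts = np.zeros(13, dtype=int)
    counts[0], counts[1] = 7, 5
    means = np.zeros(13)
    means[1] = 5.0
    prof = ms.rd_scores(ms.CensusVector("x", 3, counts),
                        _summary(means, np.ones(13)))
    assert prof.rd[0] == 1.0            # real > 0, null mean 0
    assert prof.rd[1] == 0.0            # real equals null mean
    assert prof.undefined[2:].all()     # 0/0 cases flagged
    ok = ~prof.undefined
    assert np.all(np.abs(prof.rd[ok]) <= 1.0)
    assert np.linalg.norm(prof.normalized[ok]) == pytest.approx(1.0)


def test_dimension_mismatch_rejected(cat3):
    real = ms.CensusVector("x", 3, np.zeros(13, dtype=int))
    with pytest.raises(ValueError):
        ms.z_scores(real, _summary(np.zeros(12), np.ones(12)))


def test_self_null_z_centered_on_zero(cat3):
    # a "real" network drawn from the null should have Z ~ 0 on average
    n, m, reps = 18, 50, 120
    rng = np.random.default_rng(7)
    ens = ms.er_ensemble(n, m, 300, cat3, seed=8)
    defined = ens.stds > 0
    zs = []
    for _ in range(reps):
        g = ms.er_graph(n, m, rng)
        cv = ms.count_subgraphs(g, cat3)
        prof = ms.z_scores(cv, ens)
        zs.append(prof.z)
    zs = np.array(zs)[:, defined]
    mean = zs.mean(axis=0)
    se = zs.std(axis=0, ddof=1) / np.sqrt(reps)
    # the fixed finite ensemble adds a mean-estimate error of 1/sqrt(E) in Z
    # units that does not average out over repetitions
    tol = 3.5 * np.sqrt(se ** 2 + 1.0 / 300)
    assert (np.abs(mean) < tol).all()


def test_rd_bounds_on_random_networks(cat3):
    rng = np.random.default_rng(9)
    ens = ms.er_ensemble(15, 40, 100, cat3, seed=10)
    for _ in range(20):
        cv = ms.count_subgraphs(ms.er_graph(15, 40, rng), cat3)
        prof = ms.rd_scores(cv, ens)
        ok = ~prof.undefined
        assert np.all(prof.rd[ok] >= -1.0) and np.all(prof.rd[ok] <= 1.0)


def test_profile_matrix_identical_networks(cat3):
    rec = ms.gen_er(25, 90, seed=11, name="a")
    twin = ms.NetworkRecord("b", rec.node_labels, rec.graph)
    # shared null ensemble: identical networks get exactly identical profiles
    _, shared = ms.profile_matrix([rec, twin], 3, "z", ensemble_size=100,
                                  seed=12, catalog=cat3, share_ensemble=True)
    assert shared.loc["a", "b"] == 1.0
    # independent ensembles: equal up to null-ensemble noise
    _, mat = ms.profile_matrix([rec, twin], 3, "z", ensemble_size=200,
                               seed=12, catalog=cat3)
    assert mat.loc["a", "a"] == 1.0
    assert mat.loc["a", "b"] >= 0.95


def test_profile_of_same_census_same_ensemble_is_identical(cat3):
    rec = ms.gen_er(20, 70, seed=13)
    cv = ms.count_subgraphs(rec.graph, cat3)
    ens = ms.er_ensemble(20, 70, 150, cat3, seed=14)
    a = ms.z_scores(cv, ens)
    b = ms.z_scores(cv, ens)
    ok = ~a.undefined
    assert np.array_equal(a.sp[ok], b.sp[ok])


def test_planted_ffl_dominates_profile(cat3):
    base = ms.gen_er(60, 60, seed=15)
    ffl = cat3.classes[cat3.index_of_name("feedforward loop")]
    planted = ms.plant_motifs(base, ffl, copies=20, seed=16)
    cv = ms.count_subgraphs(planted.graph, cat3)
    ens = ms.er_ensemble(60, planted.graph.arc_count, 200, cat3, seed=17)
    prof = ms.z_scores(cv, ens)
    idx = cat3.index_of_name("feedforward loop")
    ok = ~prof.undefined
    assert prof.sp[idx] == np.nanmax(prof.sp[ok])


def test_profile_matrix_needs_two_networks(cat3):
    with pytest.raises(ms.InsufficientDataError):
        ms.profile_matrix([ms.gen_er(10, 20, seed=18)], 3, catalog=cat3)
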