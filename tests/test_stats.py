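"""Rank statistics: worked values, reference agreement, invariances."""

import numpy as np
import pytest
from scipy import stats as sps

import motifsync as ms


def test_spearman_worked_examples():
    r = ms.spearman([1, 2, 3, 4], [1, 3, 2, 4])
    assert r.rho == pytest.approx(0.8)       # 1 - 6*2/(4*15)
    assert ms.spearman([1, 2, 3], [10, 20, 30]).rho == pytest.approx(1.0)
    assert ms.spearman([1, 2, 3], [3, 2, 1]).rho == pytest.approx(-1.0)
    assert ms.spearman([1, 2, 3], [10, 20, 30]).p_value == 0.0


def test_spearman_errors():
    with pytest.raises(ms.DegenerateDataError):
        ms.spearman([1, 2], [3, 4])
    with pytest.raises(ms.DegenerateDataError):
        ms.spearman([1, 2, 3], [5, 5, 5])
    with pytest.raises(ms.DegenerateDataError):
        ms.spearman([1, 2, 3], [1, 2])


def test_spearman_symmetry_and_monotone_invariance():
    rng = np.random.default_rng(1)
    x = rng.random(20)
    y = rng.random(20)
    a = ms.spearman(x, y)
    assert a.rho == pytest.approx(ms.spearman(y, x).rho)
    b = ms.spearman(np.exp(3 * x), y ** 3 + 7)
    assert a.rho == pytest.approx(b.rho)


def test_kruskal_wallis_worked_example():
    r = ms.kruskal_wallis([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
    assert r.H == pytest.approx(7.2)         # rank sums 6, 15, 24
    assert r.df == 2


def test_kruskal_wallis_identical_groups_and_errors():
    r = ms.kruskal_wallis([[1, 2, 3], [3, 1, 2]])
    assert r.H == pytest.approx(0.0)
    with pytest.raises(ms.DegenerateDataError):
        ms.kruskal_wallis([[5, 5], [5, 5]])
    with pytest.raises(ms.DegenerateDataError):
        ms.kruskal_wallis([[1, 2, 3]])


def test_kruskal_wallis_monotone_invariance():
    groups = [[1.0, 4.0, 2.5], [3.0, 8.0], [0.5, 6.0, 9.0, 2.0]]
    a = ms.kruskal_wallis(groups)
    b = ms.kruskal_wallis([np.exp(g) for g in map(np.asarray, groups)])
    assert a.H == pytest.approx(b.H)


def test_agreement_with_scipy_reference():
    rng = np.random.default_rng(2)
    for _ in range(100):
        n = int(rng.integers(5, 30))
        # integer-valued data forces ties, exercising the tie corrections
        x = rng.integers(0, 8, size=n).astype(float)
        y = rng.integers(0, 8, size=n).astype(float)
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        ours = ms.spearman(x, y)
        ref = sps.spearmanr(x, y)
        assert ours.rho == pytest.approx(ref.statistic, abs=1e-10)
        if abs(ours.rho) < 1.0:
            assert ours.p_value == pytest.approx(ref.pvalue, abs=1e-10)
        sizes = rng.integers(2, 8, size=3)
        groups = [rng.integers(0, 6, size=s).astype(float) for s in sizes]
        if len(set(np.concatenate(groups))) < 2:
            continue
        ours_kw = ms.kruskal_wallis(groups)
        ref_kw = sps.kruskal(*groups)
        assert ours_kw.H == pytest.approx(ref_kw.statistic, abs=1e-10)
        assert ours_kw.p_value == pytest.approx(ref_kw.pvalue, abs=1e-10)


def test_five_number_summary_worked_examples():
    s = ms.five_number_summary(np.arange(1, 10))
    assert s.median == 5.0
    assert s.q1 == 3.0 and s.q3 == 7.0 and s.iqr == 4.0
    s2 = ms.five_number_summary([1, 2, 3, 4, 100])
    assert s2.outliers == (100.0,)
    assert s2.upper_whisker == 4.0           # largest value inside Q3+1.5*IQR
    s3 = ms.five_number_summary([2.0, 2.0, 2.0])
    assert s3.iqr == 0.0 and s3.outliers == ()
    with pytest.raises(ValueError):
        ms.five_number_summary([])


def test_report_perfect_monotone_association(cat3, exact_sm3):
    sm = ms.SMScoreVector(exact_sm3, np.full(13, 1e-4),
                          ms.SMConfig(10, 10, 10, 0))
    # frequencies constructed as a strictly increasing function of SM score
    counts = np.argsort(np.argsort(exact_sm3)) * 3 + 1
    census = ms.CensusVector("mono", 3, counts)
    report = ms.sm_vs_frequency_report(
        sm, [census], ms.sm_quartile_classes(sm), ms.density_classes(cat3))
    assert report.spearman_sm_frequency["mono"].rho == pytest.approx(1.0)
    assert report.kw_frequency_by_sm_class["mono"].p_value < 0.1


def test_report_shuffled_censuses_center_on_zero(cat3, exact_sm3):
    sm = ms.SMScoreVector(exact_sm3, np.full(13, 1e-4),
                          ms.SMConfig(10, 10, 10, 0))
    rng = np.random.default_rng(3)
    base = np.arange(1, 14) * 2
    rhos = []
    for i in range(200):
        census = ms.CensusVector(f"s{i}", 3, rng.permutation(base))
        report = ms.sm_vs_frequency_report(sm, [census],
                                           ms.sm_quartile_classes(sm),
                                           ms.density_classes(cat3))
        rhos.append(report.spearman_sm_frequency[f"s{i}"].rho)
    assert abs(np.mean(rhos)) < 3 / np.sqrt(12 * 200)


def test_report_profile_kw_by_density(cat3, exact_sm3):
    sm = ms.SMScoreVector(exact_sm3, np.full(13, 1e-4),
                          ms.SMConfig(10, 10, 10, 0))
    rng = np.random.default_rng(4)
    census = ms.CensusVector("net", 3, rng.integers(1, 50, size=13))
    profiles = {"z": {"net": rng.normal(size=13)}}
    report = ms.sm_vs_frequency_report(sm, [census],
                                       ms.sm_quartile_classes(sm),
                                       ms.density_classes(cat3),
                                       profiles=profiles)
    per = report.kw_profile_by_density["z"]["net"]
    assert set(per) == {2, 3, 4, 5, 6}
    # singleton density classes cannot support a between-class test
    assert per[5] is None and per[6] is None


def test_report_dimension_mismatch(cat3, exact_sm3):
    sm = ms.SMScoreVector(exact_sm3, np.full(13, 1e-4),
                          ms.SMConfig(10, 10, 10, 0))
    bad = ms.CensusVector("bad", 4, np.zeros(199, dtype=int))
    with pytest.raises(ValueError):
        ms.sm_vs_frequency_report(sm, [bad], ms.sm_quartile_classes(sm),
                                  ms.density_classes(cat3))
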