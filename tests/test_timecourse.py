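"""Spline condensation, permutation functional ANOVA, FDR, and clustering."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats as ss

from stressdyn.timecourse import (
    anova_table,
    condense_course,
    condense_descriptor_table,
    courses_by_reporter,
    fdr_adjust,
    functional_anova,
    interpolate_100,
    linkage_to_newick,
    multireporter_distance,
    ward_cluster,
)

T25 = np.linspace(0, 24, 25)


def test_condense_reproduces_constant_and_linear():
    grid, v = condense_course([(T25, np.full(25, 3.7))])
    assert len(grid) == 24
    np.testing.assert_allclose(v, 3.7, atol=1e-9)
    grid, v = condense_course([(T25, 2.0 + 0.5 * T25)])
    np.testing.assert_allclose(v, 2.0 + 0.5 * grid, atol=1e-9)


def test_condense_affine_equivariance():
    rng = np.random.default_rng(0)
    y = rng.normal(size=25)
    _, v = condense_course([(T25, y)])
    _, v2 = condense_course([(T25, 3.0 * y + 1.0)])
    np.testing.assert_allclose(v2, 3.0 * v + 1.0, atol=1e-8)


def test_condense_tracks_smooth_logistic():
    f = lambda x: 1 / (1 + np.exp(-0.6 * (x - 10)))
    grid, v = condense_course([(T25, f(T25))])
    rel = np.abs(v - f(grid)).max() / (f(T25).max() - f(T25).min())
    assert rel < 0.02


def test_condense_averages_replicates():
    _, v = condense_course([(T25, np.full(25, 1.0)), (T25, np.full(25, 3.0))])
    np.testing.assert_allclose(v, 2.0, atol=1e-9)


def test_condense_needs_enough_points():
    with pytest.raises(ValueError):
        condense_course([(np.arange(5.0), np.arange(5.0))], df=8)


def test_interpolate_100_linear_and_knots():
    grid, v = interpolate_100([0, 24], [0, 24])
    assert len(v) == 100
    np.testing.assert_allclose(v, grid)
    times = np.arange(0, 25, 1.0)
    vals = np.sin(times)
    grid, v = interpolate_100(times, vals)
    # grid points that coincide with knots keep the knot value
    for i, g in enumerate(grid):
        near = np.isclose(g, times)
        if near.any():
            assert v[i] == pytest.approx(vals[near.argmax()])
    grid, v = interpolate_100([0, 10, 24], [5.0, 5.0, 5.0])
    np.testing.assert_allclose(v, 5.0)
    with pytest.raises(ValueError):
        interpolate_100([1.0], [1.0])


def test_functional_anova_identical_groups():
    res = functional_anova(np.ones((2, 50)), np.ones((3, 50)))
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_functional_anova_disjoint_constant_groups_exhaustive():
    """3v3 disjoint constants: exhaustive permutation gives the minimum
    attainable one-sided p = 1/C(6,3) = 0.05."""
    res = functional_anova(np.full((3, 100), 10.0), np.zeros((3, 100)), direction="up")
    assert res.exhaustive and res.n_permutations == 20
    assert res.p_value == pytest.approx(0.05)


def test_functional_anova_directionality():
    down_shift = functional_anova(
        np.full((3, 50), -5.0), np.zeros((3, 50)), direction="up"
    )
    assert down_shift.statistic == 0.0 and down_shift.p_value == 1.0
    two = functional_anova(
        np.full((3, 50), -5.0), np.zeros((3, 50)), direction="two_sided"
    )
    assert two.p_value <= 0.1


def test_functional_anova_input_validation():
    with pytest.raises(ValueError):
        functional_anova(np.ones((1, 50)), np.ones((3, 50)))
    with pytest.raises(ValueError):
        functional_anova(np.ones((2, 50)), np.ones((2, 40)))
    with pytest.raises(ValueError):
        functional_anova(np.ones((2, 50)), np.ones((2, 50)), direction="sideways")


def test_functional_anova_null_uniform_small():
    """Quick null calibration: p-values of same-distribution groups are
    roughly uniform (full 1000-seed calibration runs in the acceptance suite)."""
    ps = []
    for i in range(200):
        rng = np.random.default_rng(1000 + i)
        a = rng.normal(size=(4, 50))
        b = rng.normal(size=(8, 50))
        ps.append(functional_anova(a, b, direction="up").p_value)
    assert ss.kstest(ps, "uniform").pvalue > 0.01


@pytest.mark.parametrize(
    "pvals,expected",
    [
        ([0.04], [0.04]),
        ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
        ([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]),
    ],
)
def test_bh_fdr(pvals, expected):
    q, _ = fdr_adjust(pvals)
    np.testing.assert_allclose(q, expected)
    assert (q >= np.asarray(pvals) - 1e-12).all()


def test_manhattan_distance_matrix():
    a = pd.DataFrame([[0, 0, 0], [1, 2, 3]], index=["A", "B"])
    d = multireporter_distance({"R1": a})
    assert d.loc["A", "B"] == 6.0 and d.loc["A", "A"] == 0.0
    b = pd.DataFrame([[0, 0, 0], [1, 1, 0]], index=["A", "B"])
    d2 = multireporter_distance({"R1": a, "R2": b})
    assert d2.loc["A", "B"] == pytest.approx((6 + 2) / 2)


def test_distance_metric_properties():
    rng = np.random.default_rng(7)
    mats = {
        r: pd.DataFrame(rng.normal(size=(5, 12)), index=list("ABCDE"))
        for r in ("R1", "R2", "R3")
    }
    d = multireporter_distance(mats).to_numpy()
    assert np.allclose(d, d.T) and np.allclose(np.diag(d), 0)
    for i in range(5):
        for j in range(5):
            for k in range(5):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-9


def test_distance_dimension_mismatch():
    a = pd.DataFrame([[0, 0], [1, 1]], index=["A", "B"])
    b = pd.DataFrame([[0, 0, 0], [1, 1, 1]], index=["A", "B"])
    with pytest.raises(ValueError, match="dimension"):
        multireporter_distance({"R1": a, "R2": b})


def test_ward_recovers_planted_partition():
    rng = np.random.default_rng(11)
    g1 = rng.normal(0, 0.1, size=(5, 10))
    g2 = rng.normal(10, 0.1, size=(5, 10))
    vecs = pd.DataFrame(np.vstack([g1, g2]),
                        index=[f"i{k}" for k in range(10)])
    d = multireporter_distance({"R": vecs})
    labels, _ = ward_cluster(d, k=2)
    assert len(set(labels[:5])) == 1 and len(set(labels[5:])) == 1
    assert labels[0] != labels[-1]


def test_ward_duplicates_merge_at_zero_and_order_invariance():
    rng = np.random.default_rng(2)
    x = rng.normal(size=(6, 8))
    x[3] = x[0]  # duplicate item
    vecs = pd.DataFrame(x, index=[f"i{k}" for k in range(6)])
    d = multireporter_distance({"R": vecs})
    labels, z = ward_cluster(d, k=3)
    assert labels[0] == labels[3]
    assert z[0, 2] == pytest.approx(0.0, abs=1e-12)
    # permuting the input order permutes but does not change the partition
    perm = [4, 2, 0, 5, 1, 3]
    labels_p, _ = ward_cluster(d.iloc[perm, perm], k=3)
    for i, pi in enumerate(perm):
        for j, pj in enumerate(perm):
            assert (labels_p[i] == labels_p[j]) == (labels[pi] == labels[pj])
    with pytest.raises(ValueError):
        ward_cluster(d.iloc[:1, :1], k=1)


def test_newick_encoding_contains_all_leaves():
    rng = np.random.default_rng(5)
    vecs = pd.DataFrame(rng.normal(size=(4, 6)), index=list("WXYZ"))
    d = multireporter_distance({"R": vecs})
    _, z = ward_cluster(d, k=2)
    nwk = linkage_to_newick(z, list(d.index))
    assert nwk.endswith(";") and all(leaf in nwk for leaf in "WXYZ")


def test_condense_and_anova_tables_on_screen(small_descriptors):
    condensed = condense_descriptor_table(
        small_descriptors[small_descriptors["descriptor"] == "frac_2m"]
    )
    counts = condensed.groupby(
        ["compound", "conc_xcmax", "reporter", "descriptor"]
    ).size()
    assert (counts == 24).all()
    head = small_descriptors[
        (small_descriptors["reporter"] == "SRXN1")
        & (small_descriptors["conc_xcmax"].isin([0.0, 100.0]))
    ]
    table = anova_table(head, headline={"SRXN1": "frac_2m"}, n_perm=199, rng_seed=0)
    assert {"compound", "p", "q", "statistic"} <= set(table.columns)
    assert table["p"].between(0, 1).all()
    assert (table["q"] >= table["p"] - 1e-12).all()


def test_courses_by_reporter_concatenates_concentrations(small_descriptors):
    condensed = condense_descriptor_table(
        small_descriptors[small_descriptors["descriptor"].isin(
            ["frac_2m", "icam_diff_2"])]
    )
    courses = courses_by_reporter(condensed)
    assert set(courses) == {"SRXN1", "CHOP", "P21", "ICAM1"}
    n_conc = small_descriptors["conc_xcmax"].nunique() - 1  # minus control 0
    assert courses["SRXN1"].shape[1] == 24 * n_conc
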