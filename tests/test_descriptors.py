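"""Descriptor arithmetic on hand-computed micro-examples and screen tables."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from stressdyn.descriptors import (
    ControlStats,
    compute_control_stats,
    compute_descriptor_table,
    feature_slope,
    frac_positive,
    icam_fractions,
    max_over_time,
    max_summary_table,
    pi_flag,
    pi_fraction_normalized,
    scale_minmax,
)


def _control_cells(values, time_h=0.0, kind="DMSO"):
    n = len(values)
    return pd.DataFrame(
        {
            "plate_id": ["p"] * n,
            "control_kind": [kind] * n,
            "time_h": [time_h] * n,
            "gfp_intensity": values,
            "nucleus_area_px": [100.0] * n,
            "pi_overlap_area_px": [np.nan] * n,
        }
    )


def test_control_quartiles_linear_interpolation():
    stats = compute_control_stats(_control_cells(list(range(1, 12))), 0.0, min_cells=5)
    assert stats.q1_gfp == 3.5
    assert stats.q3_gfp == 8.5
    assert stats.iqr_gfp == 5.0


def test_control_stats_degenerate_and_errors():
    stats = compute_control_stats(_control_cells([100.0] * 25), 0.0)
    assert stats.mean_gfp == 100.0 and stats.sd_gfp == 0.0 and stats.iqr_gfp == 0.0
    with pytest.raises(ValueError):
        compute_control_stats(_control_cells([1.0] * 5), 0.0)  # too few cells
    with pytest.raises(ValueError):
        compute_control_stats(_control_cells([]).iloc[:0], 0.0)


def test_gfp_positive_fractions_worked_example():
    control = ControlStats("p", "DMSO", mean_gfp=100.0, sd_gfp=20.0,
                           q1_gfp=90.0, q3_gfp=110.0)
    cells = [90, 150, 210, 250, 400, 95, 100, 120, 180, 310]
    assert frac_positive(cells, control, "2m") == pytest.approx(0.40)
    assert frac_positive(cells, control, "3m") == pytest.approx(0.20)
    # threshold 100 + 3*20 = 160
    assert frac_positive(cells, control, "m3sd") == pytest.approx(0.50)
    assert frac_positive([100.0] * 5, control, "2m") == 0.0
    with pytest.raises(ValueError):
        frac_positive([], control, "2m")


@settings(max_examples=50, deadline=None, derandomize=True)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_frac_positive_scale_invariant(scale):
    """Rescaling all intensities and the control mean together leaves the
    positive fractions unchanged."""
    cells = np.array([90, 150, 210, 250, 400, 95, 100, 120, 180, 310], dtype=float)
    c1 = ControlStats("p", "DMSO", 100.0, 20.0, 90.0, 110.0)
    c2 = ControlStats("p", "DMSO", 100.0 * scale, 20.0 * scale,
                      90.0 * scale, 110.0 * scale)
    for rule in ("2m", "3m", "m3sd"):
        assert frac_positive(cells, c1, rule) == frac_positive(cells * scale, c2, rule)


def test_icam_fence_worked_example():
    control = ControlStats("p", "TNFa_DMSO", 6.0, 3.3, q1_gfp=3.5, q3_gfp=8.5)
    up, down, diff = icam_fractions([20, 20, 5, 5, 5], control, 1.5)
    # fences: 8.5 + 1.5*5 = 16 and 3.5 - 1.5*5 = -4
    assert (up, down, diff) == (0.4, 0.0, 0.4)
    up, down, diff = icam_fractions([-10, -10], control, 1.5)
    assert diff == -1.0
    with pytest.raises(ValueError):
        icam_fractions([1.0], ControlStats("p", "DMSO", 6.0, 3.3, 3.5, 8.5), 1.5)


def test_icam_diff_of_control_like_cells_matches_tail_imbalance():
    """Cells drawn from the control distribution have E[up - down] equal to
    the control distribution's own fence tail-mass difference (nonzero for
    skewed intensities — the fences are not probability-symmetric)."""
    rng = np.random.default_rng(4)
    pool = rng.lognormal(0, 0.5, size=200_000)
    q1, q3 = np.quantile(pool, [0.25, 0.75])
    control = ControlStats("p", "TNFa_DMSO", pool.mean(), pool.std(), q1, q3)
    expected = float(np.mean(pool > q3 + 1.5 * (q3 - q1))
                     - np.mean(pool < q1 - 1.5 * (q3 - q1)))
    diffs = []
    for i in range(200):
        sample = rng.lognormal(0, 0.5, size=200)
        up, down, diff = icam_fractions(sample, control, 1.5)
        assert 0 <= up <= 1 and 0 <= down <= 1 and up + down <= 1
        diffs.append(diff)
    se = np.std(diffs, ddof=1) / math.sqrt(len(diffs))
    assert abs(np.mean(diffs) - expected) < 3 * se
    # symmetric control distribution: the imbalance (and E[diff]) is ~0
    sym = rng.normal(10, 1, size=100_000)
    q1s, q3s = np.quantile(sym, [0.25, 0.75])
    ctrl_sym = ControlStats("p", "TNFa_DMSO", sym.mean(), sym.std(), q1s, q3s)
    d_sym = [icam_fractions(rng.normal(10, 1, 200), ctrl_sym, 1.5)[2]
             for _ in range(200)]
    assert abs(np.mean(d_sym)) < 0.01


def test_pi_flag_ratio_rule():
    row = pd.Series({"pi_overlap_area_px": 15.0, "nucleus_area_px": 100.0})
    assert pi_flag(row) is True
    row["pi_overlap_area_px"] = 9.0
    assert pi_flag(row) is False
    row["pi_overlap_area_px"] = 0.0
    assert pi_flag(row) is False
    row["pi_overlap_area_px"] = 10.0  # boundary is inclusive
    assert pi_flag(row) is True
    row["pi_overlap_area_px"] = np.nan
    with pytest.raises(ValueError):
        pi_flag(row)


def test_pi_fraction_normalization():
    control = ControlStats("p", "DMSO", 1, 0, 0, 0, pi_positive_fraction=0.05)
    assert pi_fraction_normalized(0.30, control) == pytest.approx(0.25)
    assert pi_fraction_normalized(0.05, control) == pytest.approx(0.0)
    assert pi_fraction_normalized(0.02, control) == pytest.approx(-0.03)


@pytest.mark.parametrize(
    "values,times,slope",
    [
        ([100, 110, 120, 130], [0, 1, 2, 3], 10.0),
        ([5, 5, 5, 5], [0, 1, 2, 3], 0.0),
        ([0, 2, 4, 6, 8], [0, 1, 2, 3, 4], 2.0),
    ],
)
def test_feature_slope_ols(values, times, slope):
    assert feature_slope(values, times) == pytest.approx(slope)


def test_feature_slope_needs_three_points():
    with pytest.raises(ValueError):
        feature_slope([1, 2], [0, 1])


def test_scale_minmax():
    np.testing.assert_allclose(scale_minmax([2, 5, 8], 2, 8), [0, 0.5, 1])
    with pytest.warns(UserWarning):
        out = scale_minmax([3, 3], 3, 3)
    np.testing.assert_allclose(out, [0, 0])


def test_max_over_time_signed_extreme():
    assert max_over_time([0, 0.2, 0.7, 0.5]) == 0.7
    assert max_over_time([-0.6, 0.1], signed_extreme=True) == -0.6
    assert max_over_time([0.0, 0.0]) == 0.0


def test_descriptor_table_structure(small_descriptors, small_screen):
    desc = small_descriptors
    lay = small_screen["layout"]
    hours = len(lay.hours)
    # fractions stay in range; ICAM diff in [-1, 1]
    frac = desc[desc["descriptor"].str.startswith("frac")]
    assert frac["value"].between(0, 1).all()
    diff = desc[desc["descriptor"].str.startswith("icam_diff")]
    assert diff["value"].between(-1, 1).all()
    inten = desc[(desc["descriptor"] == "intensity_mean") & (desc["reporter"] != "ICAM1")]
    assert inten["value"].between(0, 1).all()
    # every treated compound series covers the full hourly grid
    one = desc[(desc["compound"] == "APAP") & (desc["descriptor"] == "frac_2m")
               & (desc["reporter"] == "SRXN1") & (desc["conc_xcmax"] == 100.0)
               & (desc["replicate"] == "1")]
    assert len(one) == hours
    # control curves present for whole-curve testing
    assert (desc["compound"] == "DMSO").any()
    assert (desc["compound"] == "TNFa_DMSO").any()


def test_control_fraction_matches_lognormal_tail():
    """On control cells with mean-one lognormal noise the expected 2x-mean
    positive fraction equals the analytic lognormal tail mass."""
    from stressdyn.simulate import EffectConfig, simulate_well

    cfg = EffectConfig()
    well = simulate_well(None, 0.0, "SRXN1", 10_000, [0.0], 21, cfg)
    gfp = well["gfp_intensity"].to_numpy()
    control = ControlStats("p", "DMSO", gfp.mean(), gfp.std(ddof=1),
                           *np.quantile(gfp, [0.25, 0.75]))
    frac = frac_positive(gfp, control, "2m")
    sigma = math.sqrt(math.log(1 + cfg.noise_cv**2))
    # P(exp(sigma Z - sigma^2/2) > 2)
    from scipy.stats import norm
    p = norm.sf((math.log(2) + sigma**2 / 2) / sigma)
    assert abs(frac - p) < 3 * math.sqrt(p * (1 - p) / gfp.size)


def test_max_summary_uses_signed_extreme(small_descriptors):
    summ = max_summary_table(small_descriptors)
    icam = summ[summ["descriptor"] == "icam_diff_2"]
    assert not icam.empty
    # every summary value must occur in the underlying series
    row = icam.iloc[0]
    sub = small_descriptors[
        (small_descriptors["compound"] == row["compound"])
        & (small_descriptors["reporter"] == "ICAM1")
        & (small_descriptors["descriptor"] == "icam_diff_2")
        & (small_descriptors["conc_xcmax"] == row["conc_xcmax"])
    ]
    per_rep = sub.groupby("replicate")["value"].apply(
        lambda v: v.iloc[np.argmax(np.abs(v.to_numpy()))]
    )
    assert row["response"] == pytest.approx(per_rep.mean())


def test_cytotox_summary_death_increases_with_concentration(small_cytotox, small_screen):
    truth = small_screen["truth"]
    toxic = truth[np.isfinite(truth["tox_conc_xcmax"])]["compound_abbrev"].unique()
    assert len(toxic) > 0  # the seeded fixture draws cytotoxic compounds
    cyto = small_cytotox[small_cytotox["compound"].isin(toxic)]
    by_conc = cyto.groupby("conc_xcmax")["pi_fraction_norm"].mean()
    assert by_conc.loc[100.0] > by_conc.loc[1.0]
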