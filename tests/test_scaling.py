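import numpy as np
import pytest
from scipy import stats

from ductclones.errors import DegenerateSampleError, InsufficientDataError
from ductclones.io import CloneRecord, CloneTable
from ductclones.minimal import MinimalModelParams
from ductclones.scaling import (
    ccdf_log,
    collapse_test,
    group_moments,
    log_moments,
    lognormal_scaling_function,
    rescale,
    surviving_clone_fraction,
)
from ductclones.synth import LabellingDesign, generate_clone_table


@pytest.mark.parametrize(
    "sizes,expected",
    [
        ([1], (0.0, 0.0)),
        ([2, 8], (1.3863, 0.4805)),
        ([7, 7, 7], (np.log(7), 0.0)),
    ],
)
def test_log_moments(sizes, expected):
    mu, s2 = log_moments(sizes)
    assert mu == pytest.approx(expected[0], abs=5e-5)
    assert s2 == pytest.approx(expected[1], abs=5e-5)


def test_log_moments_uses_population_variance():
    sizes = [2, 4, 8, 16]
    _, s2 = log_moments(sizes)
    assert s2 == pytest.approx(np.log(sizes).var(ddof=0))
    assert s2 != pytest.approx(np.log(sizes).var(ddof=1))


def test_log_moments_rejects_bad_input():
    with pytest.raises(ValueError):
        log_moments([])
    with pytest.raises(ValueError):
        log_moments([1, 0])


def test_ccdf_strict_inequality_and_bounds():
    c = ccdf_log([5])
    assert c(np.log(5) - 1e-9) == 1.0
    assert c(np.log(5)) == 0.0  # strict ">": the clone itself is not larger
    c = ccdf_log([2, 4, 8])
    assert c(-1.0) == 1.0  # all sizes >= 1 so ln n >= 0
    assert c(np.log(4)) == pytest.approx(1 / 3)
    grid = np.linspace(-2, 4, 50)
    vals = c(grid)
    assert (np.diff(vals) <= 0).all()
    assert ((vals >= 0) & (vals <= 1)).all()


def test_rescale_standardises_and_is_log_scale_invariant():
    x = rescale([2, 8])
    np.testing.assert_allclose(np.sort(x), [-1.0, 1.0], atol=1e-12)
    sizes = np.array([2, 3, 5, 9, 33])
    a = rescale(sizes)
    b = rescale(sizes.astype(float) ** 2.7)  # n -> n^a leaves x unchanged
    np.testing.assert_allclose(a, b, atol=1e-9)
    assert abs(a.mean()) < 1e-9
    assert abs(a.var() - 1.0) < 1e-9
    with pytest.raises(DegenerateSampleError):
        rescale([4, 4, 4])


def test_scaling_function_values_and_symmetry():
    assert lognormal_scaling_function(0.0) == pytest.approx(0.5, abs=1e-15)
    assert lognormal_scaling_function(1.0) == pytest.approx(0.15866, abs=5e-6)
    assert lognormal_scaling_function(50.0) < 1e-100
    assert lognormal_scaling_function(-50.0) == pytest.approx(1.0, abs=1e-15)
    grid = np.linspace(-8, 8, 401)
    sym = lognormal_scaling_function(grid) + lognormal_scaling_function(-grid)
    np.testing.assert_allclose(sym, 1.0, atol=1e-12)
    # equals the standard-normal upper tail
    np.testing.assert_allclose(
        lognormal_scaling_function(grid), stats.norm.sf(grid), atol=1e-14
    )


def test_collapse_test_accepts_shared_lognormal_shape(rng):
    groups = {
        t: np.maximum(np.round(np.exp(rng.normal(mu, np.sqrt(mu / 2), 500))), 1).astype(int)
        for t, mu in [(14, 2.0), (64, 3.0), (120, 4.0)]
    }
    res = collapse_test(groups)
    assert res.collapses
    assert res.pooled_sup_deviation < 0.1


def test_collapse_test_rejects_different_shape(rng):
    lognorm = np.maximum(np.round(np.exp(rng.normal(3.0, 1.0, 500))), 1).astype(int)
    expo = np.maximum(np.round(rng.exponential(20.0, 500)), 1).astype(int)
    res = collapse_test({"a": lognorm, "b": expo})
    assert not res.collapses


def test_collapse_test_group_against_itself_has_zero_ks(rng):
    sizes = np.maximum(np.round(np.exp(rng.normal(2, 1, 100))), 1).astype(int)
    res = collapse_test({"a": sizes, "b": sizes.copy()})
    assert res.pairwise.ks_stat.iloc[0] == 0.0


def test_collapse_test_excludes_small_and_degenerate_groups(rng):
    good = np.maximum(np.round(np.exp(rng.normal(2, 1, 100))), 1).astype(int)
    groups = {"g1": good, "g2": good + 1, "small": [2, 3], "flat": [5] * 50}
    res = collapse_test(groups)
    assert set(res.excluded) == {"small", "flat"}
    with pytest.raises(InsufficientDataError):
        collapse_test({"small": [2, 3], "flat": [5] * 50})


def test_surviving_clone_fraction():
    fractions = surviving_clone_fraction({14: 100.0, 64: 40.0}, reference_day=14)
    assert fractions == {14: 1.0, 64: 0.4}
    same = surviving_clone_fraction({14: 7.0, 64: 7.0, 120: 7.0})
    assert all(v == 1.0 for v in same.values())
    with pytest.raises(ValueError):
        surviving_clone_fraction({64: 40.0}, reference_day=14)
    with pytest.raises(ValueError):
        surviving_clone_fraction({14: 0.0, 64: 1.0}, reference_day=14)


def test_surviving_fraction_from_minimal_model_near_rooting_probability():
    # at ~12 cycles descendants are mostly gone: fraction ~ 1/u within 20%
    params = MinimalModelParams(unit_size=5)
    from ductclones.minimal import simulate

    traj = simulate(params, 200_000, 12, seed=29)
    frac = traj.surviving_fraction(12)
    assert 0.16 < frac < 0.24


def test_group_moments_single_record_and_global(tiny_table):
    one = CloneTable(records=tiny_table.records[:1])
    [summary] = group_moments(one, ["mouse_id"])
    assert summary.sigma2 == 0.0
    assert summary.n_clones == 1
    [glob] = group_moments(tiny_table, [])
    assert glob.n_clones == 3
    assert glob.group_keys == ()
    assert glob.single_cell_fraction == pytest.approx(1 / 3)


def test_group_moments_unknown_key(tiny_table):
    with pytest.raises(ValueError, match="unknown group key"):
        group_moments(tiny_table, ["flavour"])


def test_group_moments_deterministic_order_and_strata():
    design = LabellingDesign(n_mice=2, clones_per_gland_at_induction=50, timepoints_days=(14, 64))
    table = generate_clone_table(design, MinimalModelParams(), seed=2)
    sums = group_moments(table, ["time_days", "mouse_id"])
    keys = [tuple(v for _, v in s.group_keys) for s in sums]
    assert keys == sorted(keys)


def test_side_branch_loss_modifier_shifts_moments():
    design = LabellingDesign(n_mice=4, clones_per_gland_at_induction=200, timepoints_days=(225,))
    params = MinimalModelParams()
    table = generate_clone_table(
        design, params, seed=6, genotype="BRCA1_TRP53", side_branch_loss_delta=-0.1
    )
    by_loc = {
        dict(s.group_keys)["location"]: s for s in group_moments(table, ["location"])
    }
    assert by_loc["side_branch"].mu > by_loc["main_duct"].mu
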