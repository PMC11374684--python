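import numpy as np
import pytest

from ductclones.errors import InsufficientDataError
from ductclones.io import CloneRecord, CloneTable, DuctalTree, PointPattern1D
from ductclones.ripley import (
    branch_level_uniformity,
    csr_envelope,
    default_radii,
    ripley_analysis,
    ripley_k_1d,
    ripley_l_normalized,
)
from ductclones.synth import PatternDesign, generate_point_pattern


def brute_force_k(pattern, radii, edge_correction="none"):
    """O(n^2) oracle for K(r), reflection handled by explicit mirroring."""
    x = pattern.positions
    D = pattern.domain_length
    n = x.size
    if edge_correction == "reflect":
        targets = np.concatenate([x, -x, 2 * D - x])
    else:
        targets = x
    out = []
    for r in radii:
        total = 0
        for i, xi in enumerate(x):
            for j, xj in enumerate(targets):
                if edge_correction == "none" and j == i:
                    continue
                if edge_correction == "reflect" and j == i:
                    continue
                if abs(xi - xj) <= r:
                    total += 1
        out.append(D * total / (n * (n - 1)))
    return np.array(out)


def test_two_coincident_points_closed_form():
    pat = PointPattern1D(positions=[0.4, 0.4], domain_length=1.0)
    np.testing.assert_allclose(
        ripley_k_1d(pat, [0.01, 0.2, 0.9], edge_correction="none"), [1.0, 1.0, 1.0]
    )


def test_two_points_at_distance_d_closed_form():
    pat = PointPattern1D(positions=[0.2, 0.6], domain_length=1.0)
    k = ripley_k_1d(pat, [0.1, 0.39, 0.4, 0.8], edge_correction="none")
    np.testing.assert_allclose(k, [0.0, 0.0, 1.0, 1.0])


def test_matches_brute_force_oracle(rng):
    pat = PointPattern1D(positions=rng.uniform(0, 100, 30), domain_length=100.0)
    radii = np.array([1.0, 5.0, 10.0, 25.0])
    for ec in ("none", "reflect"):
        np.testing.assert_allclose(
            ripley_k_1d(pat, radii, edge_correction=ec),
            brute_force_k(pat, radii, edge_correction=ec),
            atol=1e-9,
        )


def test_k_monotone_and_translation_reflection_invariant(rng):
    x = rng.uniform(10, 90, 80)
    radii = np.linspace(0.5, 20, 15)
    base = ripley_k_1d(PointPattern1D(x, 100.0), radii, edge_correction="none")
    assert (np.diff(base) >= -1e-12).all()
    shifted = ripley_k_1d(PointPattern1D(x + 5, 110.0), radii, edge_correction="none")
    # interior translation with the same pair distances: identical raw K up to
    # the domain-length prefactor
    np.testing.assert_allclose(shifted / 110.0, base / 100.0, atol=1e-12)
    mirrored = ripley_l_normalized(PointPattern1D(100.0 - x, 100.0), radii)
    original = ripley_l_normalized(PointPattern1D(x, 100.0), radii)
    np.testing.assert_allclose(mirrored, original, atol=1e-12)


def test_even_grid_l_equals_minus_r_below_spacing():
    pat = PointPattern1D(positions=np.arange(5.0, 1000.0, 10.0), domain_length=1000.0)
    radii = np.array([1.0, 4.0, 9.0])
    l_vals = ripley_l_normalized(pat, radii, edge_correction="none")
    np.testing.assert_allclose(l_vals, -radii, atol=1e-12)


def test_csr_mean_k_matches_2r(rng):
    radii = np.array([50.0, 100.0, 200.0])
    reps = np.array(
        [
            ripley_k_1d(
                PointPattern1D(rng.uniform(0, 10_000, 500), 10_000.0), radii
            )
            for _ in range(200)
        ]
    )
    mean, se = reps.mean(0), reps.std(0) / np.sqrt(200)
    assert (np.abs(mean - 2 * radii) <= 3 * se).all()


def test_insufficient_points_rejected():
    with pytest.raises(InsufficientDataError):
        ripley_k_1d(PointPattern1D([1.0], 10.0), [1.0])


def test_envelope_properties():
    radii = default_radii(1000.0, n=10)
    lo, hi = csr_envelope(50, 1000.0, radii, n_sim=199, level=0.95, seed=3)
    assert (lo <= 0).all() and (hi >= 0).all()
    lo2, hi2 = csr_envelope(50, 1000.0, radii, n_sim=199, level=0.95, seed=3)
    np.testing.assert_array_equal(lo, lo2)
    np.testing.assert_array_equal(hi, hi2)
    # level 1.0 spans the simulation extremes: wider than the 95% band
    lo_full, hi_full = csr_envelope(50, 1000.0, radii, n_sim=199, level=1.0, seed=3)
    assert (lo_full <= lo2 + 1e-12).all() and (hi_full >= hi2 - 1e-12).all()
    with pytest.raises(ValueError):
        csr_envelope(50, 1000.0, radii, n_sim=10, level=0.95)


def test_csr_patterns_stay_inside_envelope_on_average():
    # a single pattern's L(r) is strongly correlated across r, so coverage is
    # calibrated over replicates: on average >= 90% of radii inside the band
    fractions = []
    for s in range(30):
        pat = generate_point_pattern(PatternDesign(mode="csr"), seed=800 + s)
        res = ripley_analysis(pat, n_sim=99, seed=9)
        inside = (res.l_values >= res.envelope_low) & (res.l_values <= res.envelope_high)
        fractions.append(inside.mean())
    assert np.mean(fractions) >= 0.9


def test_clustered_pattern_exceeds_envelope_at_cluster_scale():
    design = PatternDesign(mode="clustered")
    pat = generate_point_pattern(design, seed=10)
    res = ripley_analysis(pat, n_sim=199, seed=11)
    near = (res.radii >= design.cluster_sd_um) & (res.radii <= 4 * design.cluster_sd_um)
    assert (res.l_values[near] > res.envelope_high[near]).any()


# --- branch-level uniformity -------------------------------------------------


def three_level_tree():
    segs = {"r": (None, 100)}
    for a in "ab":
        segs[f"r{a}"] = ("r", 50)
        for b in "ab":
            segs[f"r{a}{b}"] = (f"r{a}", 25)
    return DuctalTree(segments=segs)


def make_table(levels):
    return CloneTable(
        records=[
            CloneRecord("m", "g", "WT", "luminal", 14, 2, branch_level=l)
            for l in levels
        ]
    )


def test_uniformity_calibrated_under_slot_proportional_sampling(rng):
    tree = three_level_tree()
    # slot weights: level 0 -> 100, level 1 -> 100, level 2 -> 100;
    # under the null the test should reject at roughly its nominal 5% rate
    rejections = 0
    for _ in range(40):
        levels = rng.choice([0, 1, 2], size=500, p=[1 / 3, 1 / 3, 1 / 3])
        report = branch_level_uniformity(make_table(levels), tree, n_mc=2000, seed=1)
        if report.p_value <= 0.05:
            rejections += 1
    assert rejections <= 6  # binomial(40, 0.05): P(>6) < 1e-3


def test_uniformity_rejects_concentration_at_root():
    tree = three_level_tree()
    report = branch_level_uniformity(make_table([0] * 200), tree, seed=1)
    assert report.p_value < 0.001


def test_uniformity_degenerate_single_level():
    tree = DuctalTree(segments={"r": (None, 10)})
    report = branch_level_uniformity(make_table([0, 0, 0]), tree)
    assert report.degenerate
    assert report.p_value == 1.0


def test_uniformity_requires_level_overlap():
    tree = three_level_tree()
    with pytest.raises(ValueError):
        branch_level_uniformity(make_table([7, 8]), tree)
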