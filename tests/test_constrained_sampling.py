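import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from fluxpdf.constrained_sampling import (
    LinearConstraint,
    WeightedPopulation,
    achievable_range,
    constrained_joint_sample,
    feasible_window,
    sample_many,
    truncated_weighted_draw,
)
from fluxpdf.reference import (
    rejection_triangle_sample,
    simplex_marginal,
    triangle_density,
    triangle_weight,
)
from fluxpdf.synthetic_networks import toy_triangle


def weighted_tv(values, weights, exact_density, bins=50, support=(0.0, 1.0)):
    """TV between a weighted histogram and an exact density, comparing bin
    masses (the exact density is averaged over each bin, not evaluated at
    its center, so the check measures sampling error, not binning bias)."""
    hist, edges = np.histogram(values, bins=bins, range=support, weights=weights)
    mass = hist / weights.sum()
    fine = np.linspace(support[0], support[1], bins * 50 + 1)
    f = exact_density(fine)
    cdf = np.concatenate(([0.0], np.cumsum((f[1:] + f[:-1]) / 2 * np.diff(fine))))
    cdf /= cdf[-1]
    exact_mass = np.diff(np.interp(edges, fine, cdf))
    return 0.5 * np.abs(mass - exact_mass).sum()


# ---------------------------------------------------------------------------
# interval arithmetic


@pytest.mark.parametrize(
    "coeffs, supports, expected",
    [
        ((1, 1), [(0, 1), (0, 1)], (0, 2)),
        ((1, -1), [(0, 1), (0, 1)], (-1, 1)),
        ((), [], (0, 0)),
        ((2, -3), [(-1, 1), (0.5, 2)], (-8, 0.5)),
    ],
)
def test_achievable_range(coeffs, supports, expected):
    assert achievable_range(coeffs, supports) == pytest.approx(expected)


def test_feasible_window_first_variable():
    # target 1, three unit coefficients on [0,1]: remaining two cover [0,2]
    assert feasible_window(1.0, 1.0, (0.0, 1.0), (0.0, 2.0)) == pytest.approx((0.0, 1.0))


def test_feasible_window_after_partial_draw_matches_bruteforce():
    # residual 0.3, one remaining variable on [0,1]
    win = feasible_window(0.3, 1.0, (0.0, 1.0), (0.0, 1.0))
    grid = np.linspace(0, 1, 20001)
    ok = grid[(0.3 - grid >= 0.0) & (0.3 - grid <= 1.0)]
    assert win == pytest.approx((ok.min(), ok.max()), abs=1e-4)


finite = st.floats(-10, 10, allow_nan=False)
coeff = st.floats(0.1, 5).flatmap(lambda c: st.sampled_from([c, -c]))
support = st.tuples(finite, finite).map(lambda ab: (min(ab), max(ab)))


@settings(derandomize=True, max_examples=200)
@given(
    coeffs=st.lists(coeff, min_size=1, max_size=5),
    data=st.data(),
)
def test_achievable_range_is_tight(coeffs, data):
    """The range is attained at box vertices: evaluating the sum at the
    per-coordinate minimising/maximising endpoints reaches both ends."""
    supports = [data.draw(support) for _ in coeffs]
    lo, hi = achievable_range(coeffs, supports)
    x_min = [a if c > 0 else b for c, (a, b) in zip(coeffs, supports)]
    x_max = [b if c > 0 else a for c, (a, b) in zip(coeffs, supports)]
    assert np.dot(coeffs, x_min) == pytest.approx(lo, abs=1e-9)
    assert np.dot(coeffs, x_max) == pytest.approx(hi, abs=1e-9)
    assert lo <= hi


@settings(derandomize=True, max_examples=200)
@given(
    residual=finite,
    c=coeff,
    sup=support,
    rem=support,
    data=st.data(),
)
def test_feasible_window_sound_and_complete(residual, c, sup, rem, data):
    """Every value in the window leaves an achievable residual; every value
    of the support outside the window does not."""
    win = feasible_window(residual, c, sup, rem)
    a, b = rem
    if win is not None:
        for t in (0.0, 0.5, 1.0):
            v = win[0] + t * (win[1] - win[0])
            r = residual - c * v
            assert a - 1e-7 <= r <= b + 1e-7
    v = data.draw(st.floats(sup[0], sup[1])) if sup[0] < sup[1] else sup[0]
    if win is None or not (win[0] - 1e-9 <= v <= win[1] + 1e-9):
        r = residual - c * v
        assert r < a - 1e-12 or r > b + 1e-12


def test_feasible_window_empty_when_unreachable():
    # three variables on [0, 0.1] cannot reach 1
    rem = achievable_range((1.0, 1.0), [(0, 0.1)] * 2)
    assert feasible_window(1.0, 1.0, (0.0, 0.1), rem) is None


# ---------------------------------------------------------------------------
# truncated draws


def test_truncated_draw_law_of_large_numbers(rng):
    pop = WeightedPopulation.uniform_grid(0.0, 1.0, 100_000)
    vals, weights = [], []
    for _ in range(500):
        v, w = truncated_weighted_draw(pop, (0.0, 0.3), rng)
        vals.append(v)
        weights.append(w)
    assert all(0.0 <= v <= 0.3 for v in vals)
    # window weight is deterministic here: mass of [0, 0.3]
    assert np.allclose(weights, weights[0])
    assert weights[0] == pytest.approx(0.3, abs=3.0 / np.sqrt(100_000))


def test_truncated_draw_full_and_disjoint_windows(rng):
    pop = WeightedPopulation.uniform_grid(0.0, 1.0, 101)
    _, w = truncated_weighted_draw(pop, (-5.0, 5.0), rng)
    assert w == 1.0
    v, w = truncated_weighted_draw(pop, (2.0, 3.0), rng)
    assert v is None and w == 0.0
    v, w = truncated_weighted_draw(pop, None, rng)
    assert v is None and w == 0.0


def test_truncated_draw_requires_rng():
    pop = WeightedPopulation.uniform_grid(0.0, 1.0, 11)
    with pytest.raises(ValueError):
        truncated_weighted_draw(pop, (0.0, 1.0), None)


def test_population_rejects_degenerate_weights():
    with pytest.raises(ValueError):
        WeightedPopulation([0.0, 1.0], [0.0, 0.0])
    with pytest.raises(ValueError):
        WeightedPopulation([0.0, 1.0], [1.0, -1.0])


# ---------------------------------------------------------------------------
# joint draws: the triangle toy and the simplex


def test_triangle_weighted_density_and_weights(rng):
    con, pops = toy_triangle()
    a, w = sample_many(con, pops, 100_000, rng, solved_index=2)
    assert (w > 0).all()  # rejection-free on a satisfiable constraint
    x = a[:, 2]
    assert (x >= -1e-12).all()
    assert weighted_tv(x, w, triangle_density) < 0.02


def test_triangle_reweighting_factor_is_one_minus_y(rng):
    """Sampling z after fixing y: the window weight equals the truncated
    mass 1 - y of the uniform z-density."""
    con, pops = toy_triangle()
    for y in (0.1, 0.5, 0.9):
        win = feasible_window(1.0 - y, 1.0, (0.0, 1.0), (0.0, 1.0))
        _, w = truncated_weighted_draw(pops[1], win, rng)
        assert w == pytest.approx(triangle_weight(y), abs=0.01)


def test_triangle_matches_rejection_oracle(rng):
    """Two-sample KS between the weighted rejection-free estimator and the
    naive rejection oracle (weighted draws resampled by importance)."""
    con, pops = toy_triangle()
    a, w = sample_many(con, pops, 100_000, rng, solved_index=2)
    x_oracle, n_rejected = rejection_triangle_sample(200_000, rng)
    assert n_rejected > 0  # the naive method really does reject
    idx = rng.choice(a.shape[0], size=30_000, p=w / w.sum())
    stat = stats.ks_2samp(a[idx, 2], x_oracle)
    assert stat.pvalue > 0.01


def test_single_variable_equality_is_forced_assignment(rng):
    pop = WeightedPopulation.uniform_grid(0.0, 1.0, 101)
    con = LinearConstraint(("x",), (2.0,), 1.0)
    draw = constrained_joint_sample(con, [pop], rng=rng)
    assert draw.assignment[0] == pytest.approx(0.5)
    assert draw.weight == pytest.approx(pop.density(0.5) / 2.0)


def test_simplex_marginal_from_weighted_draws(rng):
    pop = WeightedPopulation.uniform_grid(0.0, 1.0, 500)
    con = LinearConstraint(tuple("abcde"), (1.0,) * 5, 1.0)
    a, w = sample_many(con, [pop] * 5, 200_000, rng)
    tv = weighted_tv(a[:, 0], w, lambda g: simplex_marginal(g, 5), bins=40)
    assert tv < 0.02


def test_interval_target_always_lands_inside(rng):
    pop = WeightedPopulation.uniform_grid(0.0, 1.0, 200)
    con = LinearConstraint(("a", "b", "c"), (1.0, -1.0, 0.5), (0.2, 0.4))
    a, w = sample_many(con, [pop] * 3, 20_000, rng)
    s = a @ np.array([1.0, -1.0, 0.5])
    live = w > 0
    assert live.all()
    assert (s[live] >= 0.2 - 1e-9).all() and (s[live] <= 0.4 + 1e-9).all()


def test_infeasible_constraint_gives_weight_zero_not_error(rng):
    pop = WeightedPopulation.uniform_grid(0.0, 0.1, 50)
    con = LinearConstraint(("a", "b", "c"), (1.0, 1.0, 1.0), 1.0)
    a, w = sample_many(con, [pop] * 3, 1000, rng)
    assert (w == 0).all()
    draw = constrained_joint_sample(con, [pop] * 3, rng=rng)
    assert draw.weight == 0.0


def test_weights_positive_and_finite_on_feasible_draws(rng):
    con, pops = toy_triangle(q=100)
    for _ in range(200):
        d = constrained_joint_sample(con, pops, rng=rng)
        assert np.isfinite(d.weight) and d.weight >= 0.0


def test_histogram_invariant_under_variable_reordering(rng):
    """Weighted histogram of the solved variable is unchanged (within MC
    error) when the declared order of the non-solved variables flips."""
    pop = WeightedPopulation.uniform_grid(0.0, 1.0, 300)
    con_a = LinearConstraint(("y", "z", "x"), (1.0, 2.0, 1.0), 1.0)
    con_b = LinearConstraint(("z", "y", "x"), (2.0, 1.0, 1.0), 1.0)
    a1, w1 = sample_many(con_a, [pop] * 3, 60_000, rng, solved_index=2)
    a2, w2 = sample_many(con_b, [pop] * 3, 60_000, rng, solved_index=2)
    h1, edges = np.histogram(a1[:, 2], bins=40, range=(0, 1), weights=w1)
    h2, _ = np.histogram(a2[:, 2], bins=40, range=(0, 1), weights=w2)
    d1, d2 = h1 / w1.sum(), h2 / w2.sum()
    assert 0.5 * np.abs(d1 - d2).sum() < 0.02


def test_constraint_validation():
    with pytest.raises(ValueError):
        LinearConstraint(("a",), (0.0,), 1.0)
    with pytest.raises(ValueError):
        LinearConstraint(("a", "b"), (1.0,), 1.0)
    with pytest.raises(ValueError):
        LinearConstraint(("a",), (1.0,), (0.5, 0.2))
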