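"""Dirichlet-multinomial rating model: counts, smoothing, joints, MI curves."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tailsplit import (
    GOLD_STANDARD,
    CountTableSet,
    DegenerateDistributionError,
    RatingMatrix,
    UnsupportedImputationError,
    build_count_tables,
    crossover_alpha,
    dichotomize_counts,
    discrete_mi,
    generate_rating_fixture,
    impute_missing_counts,
    joint_binary,
    joint_raw,
    map_binary,
    map_conditional,
    mi_binary_at,
    mi_curves,
    mi_raw_at,
    read_ratings,
    write_ratings,
    xi_for_alpha,
)
from oracles import binary_entropy, brute_discrete_mi


# ---------------------------------------------------------------------------
# CSV ingestion
# ---------------------------------------------------------------------------

def test_read_ratings_roundtrip(tmp_path):
    matrix = generate_rating_fixture(n_raters=59, seed=3)
    path = tmp_path / "ratings.csv"
    write_ratings(matrix, path)
    loaded = read_ratings(path)
    assert loaded.n_raters == 59
    assert loaded.n_vignettes == 12
    np.testing.assert_array_equal(loaded.scores, matrix.scores)
    np.testing.assert_array_equal(loaded.gold_standard, GOLD_STANDARD)


def test_read_ratings_small_file_and_site_column(tmp_path):
    path = tmp_path / "toy.csv"
    header = ",".join(["site"] + [f"v{i}" for i in range(1, 13)])
    path.write_text(
        header + "\n"
        + "halifax," + ",".join(["5"] * 12) + "\n"
        + "boston," + ",".join(["7"] * 12) + "\n"
    )
    m = read_ratings(path)
    assert m.n_raters == 2
    assert m.site_labels == ["halifax", "boston"]


def test_read_ratings_rejects_out_of_range_score(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text(
        ",".join(f"v{i}" for i in range(1, 13)) + "\n"
        + ",".join(["11"] + ["5"] * 11) + "\n"
    )
    with pytest.raises(ValueError, match="integers in"):
        read_ratings(path)


def test_read_ratings_rejects_wrong_vignette_count(tmp_path):
    path = tmp_path / "short.csv"
    path.write_text("v1,v2\n3,4\n")
    with pytest.raises(ValueError, match="schema"):
        read_ratings(path)


def test_missing_cells_are_dropped_not_imputed(tmp_path):
    path = tmp_path / "gaps.csv"
    row = ["5"] * 12
    row[3] = ""
    path.write_text(
        ",".join(f"v{i}" for i in range(1, 13)) + "\n" + ",".join(row) + "\n"
    )
    m = read_ratings(path)
    assert m.n_dropped_cells == 1
    tables = build_count_tables(m)
    assert tables.total == 11  # 12 cells minus the dropped one


# ---------------------------------------------------------------------------
# Count tables and imputation
# ---------------------------------------------------------------------------

def test_count_tables_tally_against_gold():
    m = RatingMatrix(
        scores=np.full((2, 2), 9.0),
        gold_standard=[9, 9],
        vignette_ids=["a", "b"],
    )
    t = build_count_tables(m)
    expected = np.zeros(11)
    expected[9] = 4
    np.testing.assert_array_equal(t.counts[9], expected)
    assert t.counts.sum() == 4


def test_count_tables_single_rating():
    m = RatingMatrix(scores=[[7.0]], gold_standard=[5], vignette_ids=["a"])
    t = build_count_tables(m)
    assert t.counts[5, 7] == 1
    assert t.counts.sum() == 1


def test_fixture_counts_conserve_total():
    m = generate_rating_fixture(n_raters=59, seed=0)
    t = build_count_tables(m)
    assert t.total == 59 * 12


def test_imputation_study_pattern():
    m = generate_rating_fixture(n_raters=10, seed=1)
    t = build_count_tables(m)
    filled = impute_missing_counts(t)
    assert set(np.flatnonzero(filled.imputed)) == {0, 2, 4, 10}
    np.testing.assert_array_equal(filled.counts[0], filled.counts[1])
    np.testing.assert_array_equal(filled.counts[10], filled.counts[9])
    np.testing.assert_allclose(
        filled.counts[2], 0.5 * (filled.counts[1] + filled.counts[3]))


def test_imputation_interior_mean_example():
    counts = np.zeros((11, 11))
    counts[1, 0] = 2
    counts[3, 1] = 2
    observed = np.zeros(11, bool)
    observed[[1, 3, 5, 6, 7, 8, 9]] = True
    counts[[5, 6, 7, 8, 9], 5] = 1
    filled = impute_missing_counts(CountTableSet(counts, observed))
    expected = np.zeros(11)
    expected[0] = 1
    expected[1] = 1
    np.testing.assert_allclose(filled.counts[2], expected)


def test_imputation_rejects_adjacent_gaps():
    counts = np.zeros((11, 11))
    observed = np.zeros(11, bool)
    observed[[1, 5, 9]] = True  # gold 2,3,4 form a run of interior gaps
    counts[[1, 5, 9], 3] = 5
    with pytest.raises(UnsupportedImputationError):
        impute_missing_counts(CountTableSet(counts, observed))


# ---------------------------------------------------------------------------
# MAP smoothing
# ---------------------------------------------------------------------------

def test_map_conditional_alpha_one_is_empirical():
    counts = np.array([0, 4, 0, 0, 6, 0, 0, 0, 0, 0, 0], float)
    np.testing.assert_allclose(map_conditional(counts, 1.0), counts / 10)


def test_map_conditional_zero_counts_is_uniform():
    np.testing.assert_allclose(map_conditional(np.zeros(11), 2.0), np.full(11, 1 / 11))


def test_map_conditional_derived_example():
    counts = np.array([0] * 9 + [3, 1], float)
    expected = np.array([1 / 15] * 9 + [4 / 15, 2 / 15])
    np.testing.assert_allclose(map_conditional(counts, 2.0), expected)


def test_map_conditional_degenerate_raises():
    with pytest.raises(DegenerateDistributionError):
        map_conditional(np.zeros(11), 0.5)


@pytest.mark.parametrize("counts, xi, expected", [
    ([5, 5], 3.0, [0.5, 0.5]),
    ([3, 1], 1.0, [0.75, 0.25]),
    ([3, 1], 2.0, [4 / 6, 2 / 6]),
])
def test_map_binary_examples(counts, xi, expected):
    np.testing.assert_allclose(map_binary(np.array(counts, float), xi), expected)


@given(
    counts=st.lists(st.integers(0, 50), min_size=11, max_size=11).filter(
        lambda c: sum(c) > 0),
    alpha=st.floats(1.0, 100.0),
)
@settings(max_examples=100, deadline=None)
def test_map_conditional_is_a_distribution(counts, alpha):
    theta = map_conditional(np.array(counts, float), alpha)
    assert (theta >= 0).all()
    assert abs(theta.sum() - 1.0) < 1e-12


# ---------------------------------------------------------------------------
# Dichotomization and joints
# ---------------------------------------------------------------------------

def test_dichotomize_counts_examples():
    counts = np.zeros((11, 11))
    counts[5, 6] = 10
    counts[5, 8] = 2
    t = CountTableSet(counts, np.ones(11, bool))
    c = dichotomize_counts(t, 7)
    np.testing.assert_array_equal(c, [[10, 2], [0, 0]])


def test_dichotomize_counts_all_low_mass():
    counts = np.zeros((11, 11))
    counts[:7, :7] = 1
    t = CountTableSet(counts, np.ones(11, bool))
    c = dichotomize_counts(t, 7)
    assert c[0, 0] == 49 and c[0, 1] == c[1, 0] == c[1, 1] == 0


@given(st.lists(st.integers(0, 20), min_size=121, max_size=121),
       st.integers(1, 10))
@settings(max_examples=60, deadline=None)
def test_dichotomization_conserves_counts(flat, tau):
    counts = np.array(flat, float).reshape(11, 11)
    t = CountTableSet(counts, np.ones(11, bool))
    assert dichotomize_counts(t, tau).sum() == counts.sum()


def test_joint_raw_identity_and_uniform():
    eye = np.eye(11)
    np.testing.assert_allclose(joint_raw(eye), eye / 11)
    uni = np.full((11, 11), 1 / 11)
    np.testing.assert_allclose(joint_raw(uni), np.full((11, 11), 1 / 121))
    assert joint_raw(uni).sum() == pytest.approx(1.0, abs=1e-12)


def test_joint_binary_prior_and_trivial_cases():
    perfect = np.eye(2)
    j = joint_binary(perfect, tau=7)
    np.testing.assert_allclose(j, np.diag([7 / 11, 4 / 11]))
    uniform = np.full((2, 2), 0.5)
    assert discrete_mi(joint_binary(uniform, tau=7)) == pytest.approx(0.0, abs=1e-12)


# ---------------------------------------------------------------------------
# Discrete MI
# ---------------------------------------------------------------------------

def test_discrete_mi_independence_is_zero():
    px = np.array([0.2, 0.3, 0.5])
    py = np.array([0.6, 0.4])
    assert discrete_mi(np.outer(px, py)) == pytest.approx(0.0, abs=1e-12)


def test_discrete_mi_diagonal_binary_is_entropy():
    joint = np.diag([4 / 11, 7 / 11])
    assert discrete_mi(joint) == pytest.approx(binary_entropy(4 / 11), abs=1e-12)
    assert discrete_mi(joint) == pytest.approx(0.65549, abs=1e-5)


def test_discrete_mi_direct_summation_example():
    joint = np.array([[0.4, 0.1], [0.1, 0.4]])
    assert discrete_mi(joint) == pytest.approx(0.19274, abs=1e-5)
    assert discrete_mi(joint) == pytest.approx(brute_discrete_mi(joint), abs=1e-14)


@given(st.lists(st.floats(0.01, 1.0), min_size=8, max_size=8))
@settings(max_examples=100, deadline=None)
def test_discrete_mi_nonnegative_and_matches_brute_force(flat):
    joint = np.array(flat).reshape(2, 4)
    joint /= joint.sum()
    mi = discrete_mi(joint)
    assert mi >= -1e-14
    assert mi == pytest.approx(brute_discrete_mi(joint), abs=1e-12)


# ---------------------------------------------------------------------------
# MI curves and crossover
# ---------------------------------------------------------------------------

def test_mi_curves_vanish_at_large_alpha(asym_tables):
    assert mi_raw_at(asym_tables, 1e6) < 1e-6
    assert mi_binary_at(asym_tables, xi_for_alpha(1e6)) < 1e-6


def test_unsmoothed_binary_mi_not_above_raw(asym_tables):
    # pure empirical estimates: coarsening cannot increase MI
    assert mi_binary_at(asym_tables, 1.0) <= mi_raw_at(asym_tables, 1.0) + 1e-12


def test_mi_curve_frame_and_xi_pairing(asym_tables):
    grid = np.geomspace(0.5, 50, 40)
    curve = mi_curves(asym_tables, grid, find_crossover=False)
    df = curve.to_frame()
    np.testing.assert_allclose(df["xi"], 11 * df["alpha"] / 2)
    assert (df["mi_raw"] >= 0).all() and (df["mi_binary"] >= 0).all()


def test_mi_curves_require_sorted_grid(asym_tables):
    with pytest.raises(ValueError):
        mi_curves(asym_tables, [2.0, 1.0])


def test_crossover_absent_when_binary_always_below():
    # parity ratings: strongly informative about the raw score but nearly
    # uninformative about the responder class, so the binary curve stays below
    counts = np.zeros((11, 11))
    for k in range(11):
        counts[k, 3 if k % 2 == 0 else 8] = 40
    t = CountTableSet(counts, np.ones(11, bool))
    assert crossover_alpha(t) is None


def test_crossover_finite_and_matches_dense_scan(asym_tables):
    cross = crossover_alpha(asym_tables)
    assert cross is not None
    # independent dense-grid oracle for the sign change
    grid = np.linspace(0.5, 100, 4000)
    gap = np.array([
        mi_binary_at(asym_tables, xi_for_alpha(a)) - mi_raw_at(asym_tables, a)
        for a in grid
    ])
    idx = np.flatnonzero((gap[:-1] <= 0) & (gap[1:] > 0))[0]
    assert grid[idx] - 0.05 <= cross <= grid[idx + 1] + 0.05
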