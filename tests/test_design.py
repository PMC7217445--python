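"""Factorial construction, orthogonality diagnostics, blocking and the
sample-size rule."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import ovichoice as oc
from ovichoice import tables
from ovichoice.design import (
    Attribute,
    DesignPlan,
    _balance_score,
    _profiles_to_matrix,
    add_opt_out,
    assign_blocks,
    check_orthogonality,
    fractional_factorial,
    full_factorial,
    min_sample_size,
)
from ovichoice.exceptions import InfeasibleDesignError, InvalidInputError


def brute_force_words(profiles):
    """Independent alias-structure oracle: every subset of columns whose
    componentwise product is constant across runs is a defining word."""
    mat = _profiles_to_matrix(profiles)
    n, k = mat.shape
    words = []
    for r in range(1, k + 1):
        for combo in itertools.combinations(range(k), r):
            prod = mat[:, combo].prod(axis=1)
            if abs(int(prod.sum())) == n:
                words.append(frozenset(combo))
    return words


@pytest.mark.parametrize(
    "n_attrs,expected",
    [(6, 64), (7, 128), (1, 2)],
)
def test_full_factorial_size(n_attrs, expected):
    attrs = [Attribute(f"x{j}") for j in range(1, n_attrs + 1)]
    profiles = full_factorial(attrs)
    assert len(profiles) == expected
    rows = {p.codes for p in profiles}
    assert len(rows) == expected  # all distinct
    if n_attrs == 1:
        assert rows == {(1,), (-1,)}


def test_full_factorial_lexicographic_and_errors():
    profiles = full_factorial([Attribute("a"), Attribute("b")])
    assert [p.codes for p in profiles] == [(1, 1), (1, -1), (-1, 1), (-1, -1)]
    with pytest.raises(InvalidInputError):
        full_factorial([])
    with pytest.raises(InvalidInputError):
        full_factorial([Attribute("a"), Attribute("a")])


@pytest.mark.parametrize("n_attrs", [6, 7])
def test_sixteen_run_fraction_is_resolution_iv(n_attrs):
    """16-run regular fractions of the 2^6 and 2^7 factorials: every
    defining word has length >= 4, so no main effect is aliased with any
    two-factor interaction (checked by brute-force alias enumeration)."""
    attrs = [Attribute(f"x{j}") for j in range(1, n_attrs + 1)]
    profiles = fractional_factorial(attrs, 16, min_resolution=4)
    assert len(profiles) == 16
    words = brute_force_words(profiles)
    assert len(words) == 2 ** (n_attrs - 4) - 1  # defining contrast subgroup
    assert min(len(w) for w in words) >= 4
    report = check_orthogonality(profiles)
    assert report.is_orthogonal_array
    assert report.resolution == 4


def test_fraction_is_closed_under_defining_relation():
    """A regular fraction is a subgroup of the full factorial: the
    componentwise product of any two runs is again a run of the fraction."""
    attrs = [Attribute(f"x{j}") for j in range(1, 7)]
    profiles = fractional_factorial(attrs, 16, min_resolution=4)
    rows = {p.codes for p in profiles}
    mat = list(rows)
    for r1 in mat[:6]:
        for r2 in mat[:6]:
            prod = tuple(int(a * b) for a, b in zip(r1, r2))
            assert prod in rows


def test_fraction_trivial_and_infeasible():
    attrs3 = [Attribute(f"x{j}") for j in range(1, 4)]
    assert len(fractional_factorial(attrs3, 8, min_resolution=4)) == 8  # full 2^3
    attrs6 = [Attribute(f"x{j}") for j in range(1, 7)]
    with pytest.raises(InfeasibleDesignError) as err:
        fractional_factorial(attrs6, 8, min_resolution=4)
    assert err.value.best_resolution == 3
    with pytest.raises(InvalidInputError):
        fractional_factorial(attrs6, 12, min_resolution=3)  # not a power of 2


def test_orthogonality_full_factorial_and_duplicate_column():
    attrs = [Attribute(f"x{j}") for j in range(1, 5)]
    profiles = full_factorial(attrs)
    report = check_orthogonality(profiles)
    assert report.is_orthogonal_array
    n = len(profiles)
    assert np.array_equal(report.cross_products, n * np.eye(4, dtype=int))
    assert report.resolution is None  # no defining words in a full factorial

    duplicated = [
        oc.Profile(profile_id=p.profile_id, codes=p.codes + (p.codes[0],))
        for p in profiles
    ]
    rep2 = check_orthogonality(duplicated)
    assert not rep2.is_orthogonal_array
    assert any("columns 0 and 4" in v for v in rep2.violations)


@settings(max_examples=20, deadline=None)
@given(k=st.integers(min_value=1, max_value=8))
def test_orthogonality_of_full_factorials_property(k):
    attrs = [Attribute(f"x{j}") for j in range(1, k + 1)]
    assert check_orthogonality(full_factorial(attrs)).is_orthogonal_array or k < 1


def test_assign_blocks_shapes_and_reproducibility():
    attrs = [Attribute(f"x{j}") for j in range(1, 7)]
    profiles = fractional_factorial(attrs, 16, min_resolution=4)
    plan = assign_blocks(profiles, 4, seed=7, attributes=attrs)
    assert plan.block_sizes() == [4, 4, 4, 4]
    plan2 = assign_blocks(profiles, 4, seed=7, attributes=attrs)
    assert plan.block_assignment == plan2.block_assignment
    assert plan.positions == plan2.positions
    with pytest.raises(InvalidInputError):
        assign_blocks(profiles, 3, seed=7, attributes=attrs)
    single = assign_blocks(profiles[:4], 1, seed=0)
    assert single.block_sizes() == [4]


def test_assign_blocks_beats_random_median():
    """The seeded search should be at least as balanced as the median of
    plain random assignments (Monte-Carlo comparison oracle)."""
    attrs = [Attribute(f"x{j}") for j in range(1, 7)]
    profiles = fractional_factorial(attrs, 16, min_resolution=4)
    mat = _profiles_to_matrix(profiles)
    plan = assign_blocks(profiles, 4, seed=7, attributes=attrs)
    ids = [p.profile_id for p in profiles]
    chosen = np.array([plan.block_assignment[i] for i in ids])
    chosen_score = _balance_score(mat, chosen, 4)

    rng = np.random.default_rng(99)
    base = np.repeat(np.arange(4), 4)
    scores = []
    for _ in range(1000):
        perm = rng.permutation(16)
        assignment = np.empty(16, dtype=int)
        assignment[perm] = base
        scores.append(_balance_score(mat, assignment, 4))
    assert chosen_score <= np.median(scores)


def test_add_opt_out_counts_idempotence_roundtrip(tmp_path):
    attrs = [Attribute(f"x{j}") for j in range(1, 7)]
    profiles = fractional_factorial(attrs, 16, min_resolution=4)
    plan = add_opt_out(assign_blocks(profiles, 4, seed=7, attributes=attrs))
    frame = plan.to_frame()
    per_block = frame.groupby("block").size()
    assert (per_block == 5).all()  # 4 designed + 1 opt-out
    assert frame["is_opt_out"].sum() == 4

    again = add_opt_out(plan)
    assert again.to_frame()["is_opt_out"].sum() == 4  # idempotent

    text = plan.to_json(tmp_path / "plan.json")
    back = DesignPlan.from_json(tmp_path / "plan.json")
    assert back.opt_out == plan.opt_out
    assert back.block_assignment == plan.block_assignment
    assert back.positions == plan.positions
    assert [p.codes for p in back.profiles] == [p.codes for p in plan.profiles]
    assert DesignPlan.from_json(text).opt_out == plan.opt_out


@pytest.mark.parametrize(
    "c,t,a,expected",
    [(2, 1, 4, 250), (2, 1, 1, 1000), (2, 4, 4, 63)],
)
def test_min_sample_size(c, t, a, expected):
    assert min_sample_size(c=c, t=t, a=a) == expected


def test_min_sample_size_errors():
    with pytest.raises(InvalidInputError):
        min_sample_size(c=0, t=1, a=4)
    with pytest.raises(InvalidInputError):
        min_sample_size(c=2, t=-1, a=4)


@settings(max_examples=50, deadline=None)
@given(
    c=st.integers(min_value=2, max_value=10),
    t=st.integers(min_value=1, max_value=20),
    a=st.integers(min_value=1, max_value=10),
)
def test_min_sample_size_monotonicity(c, t, a):
    n = min_sample_size(c=c, t=t, a=a)
    assert min_sample_size(c=c + 1, t=t, a=a) >= n  # more levels -> larger N
    assert min_sample_size(c=c, t=t + 1, a=a) <= n  # more tasks -> smaller N
    assert min_sample_size(c=c, t=t, a=a + 1) <= n
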