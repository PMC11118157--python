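"""Spearman/Mann-Whitney machinery against independent oracles."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy import stats

from psoriscreen import (
    build_change_frames,
    correlation_matrix,
    export_heatmap_table,
    mann_whitney_u,
    significance_stars,
    spearman_p,
    spearman_rho,
    spearman_test,
    subgroup_analyses,
)
from psoriscreen.association import benjamini_hochberg
from psoriscreen.model import CohortDataset

from conftest import tiny_cohort


# ---------------------------------------------------------------- oracles

def midrank(values):
    """Brute-force average ranks, O(n^2), independent of scipy."""
    out = []
    for v in values:
        below = sum(1 for w in values if w < v)
        equal = sum(1 for w in values if w == v)
        out.append(below + (equal + 1) / 2.0)
    return out


def pearson(x, y):
    mx, my = sum(x) / len(x), sum(y) / len(y)
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    return sxy / math.sqrt(sxx * syy)


def spearman_oracle(x, y):
    return pearson(midrank(x), midrank(y))


def exact_spearman_p_oracle(rho, n):
    """Full n!-enumeration of rho over untied rankings."""
    base = list(range(1, n + 1))
    vals = [pearson(base, list(p)) for p in itertools.permutations(base)]
    return sum(abs(v) >= abs(rho) - 1e-12 for v in vals) / len(vals)


def mwu_oracle(a, b):
    """U of group a and two-sided p by enumerating all labelings."""
    pooled = list(a) + list(b)
    ranks = midrank(pooled)
    na = len(a)

    def u_of(idx):
        return sum(ranks[i] for i in idx) - na * (na + 1) / 2.0

    u_obs = u_of(range(na))
    mu = na * len(b) / 2.0
    labelings = list(itertools.combinations(range(len(pooled)), na))
    p = sum(abs(u_of(c) - mu) >= abs(u_obs - mu) - 1e-12 for c in labelings) / len(labelings)
    return u_obs, p


# ---------------------------------------------------------------- spearman

def test_perfect_monotone_and_antitone():
    assert spearman_rho([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)
    assert spearman_rho([1, 2, 3, 4], [40, 30, 20, 10]) == pytest.approx(-1.0)


def test_tied_data_matches_midrank_oracle():
    x, y = [1, 2, 2, 4], [3, 1, 1, 2]
    assert spearman_rho(x, y) == pytest.approx(spearman_oracle(x, y), rel=1e-12)


@given(st.data())
def test_random_vectors_match_oracle(data):
    n = data.draw(st.integers(min_value=3, max_value=12))
    x = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
    y = data.draw(st.lists(st.integers(0, 5), min_size=n, max_size=n))
    if len(set(x)) < 2 or len(set(y)) < 2:
        return
    assert spearman_rho(x, y) == pytest.approx(spearman_oracle(x, y), rel=1e-9)


@given(
    xi=st.lists(st.integers(-400, 400), min_size=4, max_size=15, unique=True),
    yi=st.lists(st.integers(-400, 400), min_size=15, max_size=15, unique=True),
)
def test_rho_invariant_under_monotone_transforms(xi, yi):
    n = len(xi)
    xs = [v / 10 for v in xi]
    y = [v / 10 for v in yi[:n]]
    base = spearman_rho(xs, y)
    assert spearman_rho([math.exp(v / 10) for v in xs], y) == pytest.approx(base, abs=1e-9)
    assert spearman_rho(xs, [3 * v + 1 for v in y]) == pytest.approx(base, abs=1e-9)
    assert spearman_rho([v**3 for v in xs], [math.atan(v) for v in y]) == pytest.approx(
        base, abs=1e-9
    )


def test_constant_vector_rejected():
    with pytest.raises(ValueError, match="constant"):
        spearman_rho([1, 1, 1], [1, 2, 3])
    with pytest.raises(ValueError):
        spearman_rho([1, 2], [1, 2, 3])


def test_spearman_p_null_center():
    assert spearman_p(0.0, 44) == pytest.approx(1.0)
    assert spearman_p(0.0, 6) == pytest.approx(1.0)


def test_spearman_p_t_branch_worked_value():
    assert spearman_p(0.22, 44) == pytest.approx(0.152, abs=0.005)


def test_spearman_p_exact_matches_enumeration():
    for rho in (1.0, 0.9, 0.3, -0.7):
        assert spearman_p(rho, 5) == pytest.approx(exact_spearman_p_oracle(rho, 5), abs=1e-12)


def test_perfect_rho_on_t_branch_returns_tiny_positive():
    p = spearman_p(1.0, 20)
    assert 0 < p < 1e-300


def test_t_and_exact_branches_agree_for_n8_n9():
    """Exhaustive over every achievable rho; the largest discrepancy
    (0.024 at n=8) sits right next to the null where both p ~ 1."""
    from psoriscreen.association import _exact_rho_distribution

    for n in (8, 9):
        for rho in np.unique(_exact_rho_distribution(n)):
            if abs(rho) == 1.0:
                continue
            assert spearman_p(rho, n) == pytest.approx(
                spearman_p(rho, n, exact_n_max=2), abs=0.025
            )


def test_spearman_test_selects_method_by_n():
    assert spearman_test([1, 2, 3, 4], [1, 3, 2, 4]).method == "exact_permutation"
    x = list(range(12))
    assert spearman_test(x, [v + (v % 3) for v in x]).method == "t_approx"


# ------------------------------------------------------------ mann-whitney

def test_mwu_symmetric_identical_groups():
    u, _ = mann_whitney_u([1, 2, 3, 4], [1, 2, 3, 4])
    assert u == 4 * 4 / 2


def test_mwu_complete_separation_exact_p():
    u, p = mann_whitney_u([1, 2, 3], [10, 20, 30])
    assert u == 0.0
    assert p == pytest.approx(0.1)  # 2 / C(6,3)


def test_mwu_empty_group_is_error():
    with pytest.raises(ValueError):
        mann_whitney_u([], [1.0])


@given(st.data())
def test_mwu_matches_enumeration_oracle(data):
    na = data.draw(st.integers(min_value=1, max_value=5))
    nb = data.draw(st.integers(min_value=1, max_value=10 - na))
    a = data.draw(st.lists(st.integers(0, 4), min_size=na, max_size=na))
    b = data.draw(st.lists(st.integers(0, 4), min_size=nb, max_size=nb))
    u, p = mann_whitney_u(a, b)
    u_exp, p_exp = mwu_oracle(a, b)
    assert u == pytest.approx(u_exp)
    assert p == pytest.approx(p_exp, abs=1e-12)


def test_mwu_large_samples_use_tie_corrected_normal():
    rng = np.random.default_rng(3)
    a = rng.integers(0, 8, size=12).astype(float)
    b = rng.integers(1, 9, size=15).astype(float)
    u, p = mann_whitney_u(a, b)
    _, p_ref = stats.mannwhitneyu(
        a, b, alternative="two-sided", method="asymptotic", use_continuity=False
    )
    assert p == pytest.approx(float(p_ref), rel=1e-12)


# ------------------------------------------------------------- matrices

def test_matrix_diagonal_symmetry_and_headline_cell(cohort):
    frames = build_change_frames(cohort)
    m = correlation_matrix(frames["rate"], "rate")
    for v in m.variables:
        assert m.rho(v, v) == 1.0
    for a in m.variables:
        for b in m.variables:
            assert m.cell(a, b) is m.cell(b, a)
    cell = m.cell("PASI", "IL-13")
    assert cell.n == 44
    assert cell.rho == pytest.approx(-0.48, abs=0.03)
    wide = m.to_wide_frame("rho")
    assert np.allclose(wide.values, wide.values.T, equal_nan=True)


def test_pairwise_deletion_keeps_uncensored_cells(cohort):
    frames = build_change_frames(cohort)
    m = correlation_matrix(frames["difference"], "difference")
    assert m.cell("PASI", "IFN-g").n == 44
    # both of patient A's courses drop from the IL-4-ratio cell only
    assert m.cell("PASI", "IFN-g/IL-4").n == 42
    assert m.cell("PASI", "IL-4").n == 43


def test_low_n_cell_reported_undefined_not_raised():
    ds = tiny_cohort(
        {
            "p1": {"induced": {"IFN-g": 10, "IL-13": 1}, "ada": {"IFN-g": 8, "IL-13": 1.2}},
            "p2": {"induced": {"IFN-g": 20, "IL-13": 2}, "ust": {"IFN-g": 15, "IL-13": 2.1}},
        }
    )
    frames = build_change_frames(ds, ("IFN-g", "IL-13"))
    m = correlation_matrix(frames["rate"], "rate")
    assert m.cell("PASI", "IFN-g") is None  # only 2 complete pairs


def test_by_disease_strata(cohort):
    mats = subgroup_analyses(cohort, "by_disease")
    assert [m.subgroup for m in mats] == ["PsO-only", "PsO-only", "PsO+PsA", "PsO+PsA"]
    pso_rate = mats[0]
    assert pso_rate.n_rows == 20  # courses of the 10 PsO-only patients
    psa_rate = mats[2]
    assert psa_rate.n_rows == 24


def test_by_biologic_strata(cohort):
    mats = subgroup_analyses(cohort, "by_biologic")
    ust = [m for m in mats if m.subgroup == "ust" and m.mode == "rate"]
    assert len(ust) == 1 and ust[0].n_rows == 15
    empty = subgroup_analyses(
        CohortDataset(cohort.patients, (), ()), "by_biologic"
    )
    assert empty == []


def test_heatmap_table_and_stars(cohort):
    frames = build_change_frames(cohort)
    m = correlation_matrix(frames["rate"], "rate", variables=["PASI", "IL-13"])
    long = export_heatmap_table(m)
    assert len(long) == 1  # one off-diagonal pair
    assert significance_stars(0.047) == "*"
    assert significance_stars(0.0099) == "**"
    assert significance_stars(0.0001) == "***"
    assert significance_stars(0.5) == ""
    full = export_heatmap_table(correlation_matrix(frames["rate"], "rate"))
    assert set(full["var_a"]) | set(full["var_b"]) >= {"PASI", "IFN-g", "IL-13"}


def test_benjamini_hochberg_matches_scipy():
    p = [0.001, 0.02, 0.04, 0.2, 0.9]
    assert benjamini_hochberg(p) == pytest.approx(
        list(stats.false_discovery_control(p, method="bh"))
    )


def test_heatmap_rendering(tmp_path, cohort):
    from psoriscreen.association import plot_heatmap

    frames = build_change_frames(cohort)
    m = correlation_matrix(frames["rate"], "rate", variables=["PASI", "IFN-g", "IL-13"])
    out = tmp_path / "h.png"
    plot_heatmap(m, out)
    assert out.stat().st_size > 0
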