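"""Reporter-count t procedures, the multiplicative synergy model, Fisher rescue
tests and behavioral index formulas."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from ciliareg._utils import bh_adjust
from ciliareg.genstats import (
    ReporterCounts,
    behavior_index,
    dauer_fold_induction,
    expected_multiplicative,
    fold_changes,
    pairwise_reporter_tests,
    regional_reporter_tests,
    rescue_test,
    synergy_test,
)
from ciliareg.synthetic import SynthConfig, synth_reporter_counts


def group(name, values, region=None):
    return ReporterCounts(genotype=name, values=np.asarray(values), region=region)


# ---------------------------------------------------------------------------
# pairwise t tests
# ---------------------------------------------------------------------------

def test_identical_groups_give_p_one():
    df = pairwise_reporter_tests([group("a", [10, 12, 11]), group("b", [10, 12, 11])])
    assert df.loc[0, "t"] == pytest.approx(0.0)
    assert df.loc[0, "p_raw"] == pytest.approx(1.0)


def test_two_group_t_matches_closed_form():
    a, b = [10, 12, 11], [2, 3, 2]
    df = pairwise_reporter_tests([group("a", a), group("b", b)])
    # variances are homogeneous here, so the pooled two-sample t applies
    ref = stats.ttest_ind(a, b, equal_var=True)
    assert df.loc[0, "t"] == pytest.approx(ref.statistic)
    assert df.loc[0, "p_raw"] == pytest.approx(ref.pvalue)
    assert bool(df.loc[0, "pooled_variance"])


def test_bonferroni_over_all_pairs():
    groups = [group("a", [1, 2, 3]), group("b", [4, 5, 6]), group("c", [7, 8, 9])]
    df = pairwise_reporter_tests(groups)
    assert len(df) == 3
    assert np.allclose(df["p_adjusted"], np.minimum(df["p_raw"] * 3, 1.0))


def test_welch_selected_for_unequal_variances():
    rng = np.random.default_rng(0)
    a = rng.normal(10, 0.1, 20)
    b = rng.normal(10, 8.0, 20)
    df = pairwise_reporter_tests([group("a", np.abs(a)), group("b", np.abs(b))])
    assert not bool(df.loc[0, "pooled_variance"])


def test_small_group_rejected():
    with pytest.raises(ValueError):
        pairwise_reporter_tests([group("a", [1]), group("b", [2, 3])])


# ---------------------------------------------------------------------------
# regional one-tailed tests with BH
# ---------------------------------------------------------------------------

def test_bh_step_up_hand_case():
    assert np.allclose(bh_adjust([0.01, 0.02, 0.04]), [0.03, 0.03, 0.04])


def test_bh_properties():
    rng = np.random.default_rng(2)
    p = rng.uniform(size=30)
    q = bh_adjust(p)
    assert np.all(q >= p)                      # never below raw p
    order = np.argsort(p)
    assert np.all(np.diff(q[order]) >= -1e-12)  # monotone in rank order


def test_regional_identical_groups_no_rejections():
    regions = {r: (group("mut", [5, 6, 7], r), group("ctl", [5, 6, 7], r))
               for r in ("head", "tail", "mid")}
    df = regional_reporter_tests(regions)
    assert not df["rejected"].any()


def test_regional_shifted_region_detected_with_power():
    """A region where the mutant is shifted down by 3 sigma is rejected with
    power > 0.9 at n = 10 animals."""
    rng = np.random.default_rng(4)
    detected = 0
    n_rep = 50
    for _ in range(n_rep):
        regions = {}
        for r in ("r1", "r2", "r3", "r4", "r5"):
            ctl = rng.normal(30, 3, 10).round()
            shift = 9 if r == "r3" else 0
            mut = np.clip(rng.normal(30 - shift, 3, 10).round(), 0, None)
            regions[r] = (group("mut", mut, r), group("ctl", ctl, r))
        df = regional_reporter_tests(regions)
        detected += bool(df.loc[df["region"] == "r3", "rejected"].iloc[0])
    assert detected / n_rep > 0.9


# ---------------------------------------------------------------------------
# fold changes and the multiplicative expectation
# ---------------------------------------------------------------------------

def test_fold_changes_hand_case():
    groups = [group("ref", [40, 60]), group("mut", [20, 30])]
    fcs = fold_changes(groups, "ref")
    assert fcs["mut"].mean_fc == pytest.approx(0.5)
    assert fcs["mut"].fold_changes == pytest.approx((0.4, 0.6))
    assert fcs["ref"].mean_fc == pytest.approx(1.0)


def test_fold_changes_scale_invariance():
    groups = [group("ref", [40, 60]), group("mut", [20, 30])]
    scaled = [group("ref", [280, 420]), group("mut", [140, 210])]
    a = fold_changes(groups, "ref")
    b = fold_changes(scaled, "ref")
    for name in ("ref", "mut"):
        assert a[name].fold_changes == pytest.approx(b[name].fold_changes)


def test_expected_multiplicative_formula():
    fcs = fold_changes([group("ref", [100] * 3),
                        group("a", [40, 50, 60]),
                        group("b", [70, 80, 90])], "ref")
    a, b = fcs["a"], fcs["b"]
    E, sd = expected_multiplicative(a, b)
    assert E == pytest.approx(a.mean_fc * b.mean_fc)
    assert sd == pytest.approx(E * (a.rel_err + b.rel_err))
    # stated arithmetic example: 0.5 x 0.8 with rel errs 0.2 and 0.125
    from ciliareg.genstats import FoldChangeStat
    fa = FoldChangeStat("a", 0.5, 0.1, (0.5,))
    fb = FoldChangeStat("b", 0.8, 0.1, (0.8,))
    E2, sd2 = expected_multiplicative(fa, fb)
    assert (E2, sd2) == (pytest.approx(0.4), pytest.approx(0.4 * 0.325))


def test_expected_multiplicative_identity_and_symmetry():
    from ciliareg.genstats import FoldChangeStat
    one = FoldChangeStat("one", 1.0, 0.0, (1.0,))
    other = FoldChangeStat("x", 0.6, 0.12, (0.6,))
    E, sd = expected_multiplicative(one, other)
    assert E == pytest.approx(0.6) and sd == pytest.approx(0.6 * 0.2)
    assert expected_multiplicative(one, one) == (pytest.approx(1.0), pytest.approx(0.0))
    assert expected_multiplicative(other, one) == expected_multiplicative(one, other)


def test_expected_multiplicative_quadrature_mode():
    from ciliareg.genstats import FoldChangeStat
    fa = FoldChangeStat("a", 0.5, 0.15, (0.5,))
    fb = FoldChangeStat("b", 0.8, 0.32, (0.8,))
    _, sd = expected_multiplicative(fa, fb, error_mode="quadrature")
    assert sd == pytest.approx(0.4 * math.hypot(0.3, 0.4))


# ---------------------------------------------------------------------------
# synergy test
# ---------------------------------------------------------------------------

def test_synergy_mean_equal_to_expectation():
    ref = group("ref", [100] * 5)
    triple = group("tri", [30, 50, 40, 30, 50])  # mean fc exactly 0.4
    res = synergy_test(triple, ref, expected_fc=0.4)
    assert res.t_statistic == pytest.approx(0.0)
    assert res.p_value == pytest.approx(1.0)
    assert res.verdict == "consistent_with_multiplicative"


def test_synergy_type_one_error_near_nominal():
    """Under the multiplicative Poisson null, the one-sample t against the true
    multiplicative expectation rejects at its nominal 0.05 level, in
    [0.03, 0.07] over 500 replicates.  (The test treats E as fixed by design;
    an estimated E adds its own sampling error, which the conservative mode
    exists to absorb.)"""
    rejections = 0
    n_rep = 500
    fixed_ref = group("ref", [60] * 10)  # the true reference mean, held fixed
    for seed in range(n_rep):
        cfg = SynthConfig(seed=10_000 + seed, reporter_interaction=1.0)
        groups, truth = synth_reporter_counts(cfg)
        by = {g.genotype: g for g in groups}
        res = synergy_test(by[truth["triple"]], fixed_ref,
                           truth["expected_triple_fc"])
        rejections += res.p_value < 0.05
    assert 0.03 <= rejections / n_rep <= 0.07


def test_synergy_power_at_strong_interaction():
    """A strong synergistic loss (interaction 0.2) is detected with power
    > 0.9 at n = 10 animals per group."""
    detected = 0
    n_rep = 200
    for seed in range(n_rep):
        cfg = SynthConfig(seed=50_000 + seed, reporter_interaction=0.2)
        groups, truth = synth_reporter_counts(cfg)
        by = {g.genotype: g for g in groups}
        fcs = fold_changes(groups, truth["reference"])
        names = list(cfg.reporter_multipliers)
        E, sd_E = expected_multiplicative(fcs[names[0]], fcs[names[1]])
        res = synergy_test(by[truth["triple"]], by[truth["reference"]], E,
                           sd_expected=sd_E)
        detected += res.verdict == "synergistic_loss"
    assert detected / n_rep > 0.9


def test_synergy_zero_variance_degenerate_handling():
    ref = group("ref", [100] * 4)
    flat = group("tri", [40, 40, 40, 40])
    same = synergy_test(flat, ref, expected_fc=0.4)
    assert same.p_value == 1.0 and same.verdict == "consistent_with_multiplicative"
    diff = synergy_test(flat, ref, expected_fc=0.8)
    assert diff.verdict == "degenerate"


def test_synergy_conservative_mode_widens_test():
    ref = group("ref", [100] * 6)
    triple = group("tri", [30, 34, 28, 33, 29, 31])
    plain = synergy_test(triple, ref, expected_fc=0.5)
    wide = synergy_test(triple, ref, expected_fc=0.5, sd_expected=0.1,
                        conservative=True)
    assert wide.p_value > plain.p_value


# ---------------------------------------------------------------------------
# rescue / Fisher
# ---------------------------------------------------------------------------

def fisher_two_sided_oracle(table):
    """Exhaustive hypergeometric enumeration of the two-sided p-value."""
    a, b = table[0]
    c, d = table[1]
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def prob(k):
        return (math.comb(r1, k) * math.comb(r2, c1 - k)) / math.comb(n, c1)

    p_obs = prob(a)
    return sum(prob(k) for k in range(max(0, c1 - r2), min(r1, c1) + 1)
               if prob(k) <= p_obs * (1 + 1e-9))


def test_fisher_no_association():
    odds, p = rescue_test([[5, 5], [5, 5]])
    assert p == pytest.approx(1.0)
    assert odds == pytest.approx(1.0)


def test_fisher_matches_enumeration_oracle():
    rng = np.random.default_rng(13)
    tables = [[[9, 1], [2, 8]]]
    for _ in range(40):
        tables.append(rng.integers(0, 11, size=(2, 2)).tolist())
    for t in tables:
        if sum(map(sum, t)) == 0:
            continue
        _, p = rescue_test(np.asarray(t))
        assert p == pytest.approx(fisher_two_sided_oracle(t), abs=1e-10)


def test_fisher_zero_cell_degenerate():
    odds, p = rescue_test([[10, 0], [3, 7]])
    assert 0 <= p <= 1 and np.isinf(odds)
    with pytest.raises(ValueError):
        rescue_test([[1, 2], [3, -1]])


# ---------------------------------------------------------------------------
# behavior indexes
# ---------------------------------------------------------------------------

def test_response_index_formula():
    idx = behavior_index("response", responses=10, strokes=50)
    assert idx.value == pytest.approx(0.2)


def test_chemotaxis_bound_attained():
    idx = behavior_index("chemotaxis_quadrant", test_quadrants=40,
                         control_quadrants=0, total=40)
    assert idx.value == 1.0


def test_dauer_fold_induction_contrast():
    wt = dauer_fold_induction(
        behavior_index("dauer_fraction", dauers=30, scored=100),
        behavior_index("dauer_fraction", dauers=5, scored=100))
    mut = dauer_fold_induction(
        behavior_index("dauer_fraction", dauers=15, scored=100),
        behavior_index("dauer_fraction", dauers=5, scored=100))
    assert wt == pytest.approx(6.0) and mut == pytest.approx(3.0)


def test_unknown_assay_and_zero_denominator():
    with pytest.raises(ValueError):
        behavior_index("flying", height=3)
    with pytest.raises(ValueError):
        behavior_index("response", responses=1, strokes=0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 100), st.integers(0, 100), st.integers(1, 100))
def test_signed_indexes_respect_bounds(t, c, extra):
    total = t + c + extra
    for assay, kw in [
        ("chemotaxis_quadrant", dict(test_quadrants=t, control_quadrants=c, total=total)),
        ("chemotaxis_halves", dict(test_half=t, control_half=c, total=total)),
        ("avoidance_sectors", dict(sectors_ab=t, sectors_ef=c, total=total)),
    ]:
        assert -1 <= behavior_index(assay, **kw).value <= 1


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.integers(0, 100), st.integers(1, 100))
def test_ratio_indexes_respect_bounds(k, n):
    k = min(k, n)
    assert 0 <= behavior_index("response", responses=k, strokes=n).value <= 1
    assert 0 <= behavior_index("avoidance_drop", responses=k, drops=n).value <= 1
    assert 0 <= behavior_index("dauer_fraction", dauers=k, scored=n).value <= 1
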