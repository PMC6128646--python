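"""Gating cascade, GFP classification and competitive growth ratios."""

import itertools

import numpy as np
import pandas as pd
import pytest

from toxprof.flow import (
    GateConfig,
    GFPCounts,
    apply_gates,
    classify_gfp,
    growth_ratio,
    read_events,
    replicate_test,
)
from toxprof.synthetic import FlowSimConfig, competition_fractions, simulate_flow_events


def _sample(fractions, n=20_000, seed=0, **kw):
    return simulate_flow_events(FlowSimConfig(n_events=n, fractions=fractions, seed=seed, **kw))


LIVE_ONLY = {"gfp_pos": 0.5, "gfp_neg": 0.5}
WITH_JUNK = {"gfp_pos": 0.48, "gfp_neg": 0.48, "doublet": 0.02, "debris": 0.02}


# ---------------------------------------------------------------------------
# gating


def test_all_live_singlets_pass_with_negligible_attrition():
    gated, report = apply_gates(_sample(LIVE_ONLY))
    assert report.attrs["total_attrition"] < 0.005
    assert len(gated) > 19_900


def test_doublet_debris_attrition_in_expected_band():
    """4% doublets+debris leaves total gate attrition in the 3-5% band."""
    _, report = apply_gates(_sample(WITH_JUNK, seed=3))
    assert 0.03 <= report.attrs["total_attrition"] <= 0.05


def test_retained_events_are_live_singlets():
    events = _sample(
        {"gfp_pos": 0.45, "gfp_neg": 0.45, "dead": 0.04, "doublet": 0.03, "debris": 0.03},
        seed=5,
    )
    gated, _ = apply_gates(events)
    live = gated["label"].isin(["gfp_pos", "gfp_pos_lost", "gfp_neg"])
    assert live.mean() >= 0.99


def test_gate_order_independence():
    """Intersection semantics: the retained set ignores gate order."""
    events = _sample(WITH_JUNK, n=5000, seed=9)
    config = GateConfig()
    masks = {
        "v": events["DAPI"] <= config.dapi_max,
        "b": events["FSC_A"].between(*config.fsc_a_bounds)
        & events["SSC"].between(*config.ssc_bounds),
        "d": (events["FSC_A"] / events["FSC_H"]).between(*config.doublet_ratio_bounds),
    }
    gated, _ = apply_gates(events, config)
    for perm in itertools.permutations("vbd"):
        running = events
        for g in perm:
            running = running[masks[g].reindex(running.index)]
        pd.testing.assert_frame_equal(running, gated)


def test_all_events_removed_is_rejected():
    events = _sample(LIVE_ONLY, n=200)
    with pytest.raises(ValueError, match="uninterpretable"):
        apply_gates(events, GateConfig(dapi_max=1e-6))


def test_event_table_validation(tmp_path):
    with pytest.raises(ValueError, match="missing columns"):
        apply_gates(pd.DataFrame({"FSC_A": [1.0]}))
    events = _sample(LIVE_ONLY, n=100)
    path = tmp_path / "ev.csv"
    events.to_csv(path, index=False)
    assert len(read_events(path)) == 100


# ---------------------------------------------------------------------------
# GFP classification


def test_fitc_thresholds():
    base = {"FSC_A": 500.0, "FSC_H": 500.0, "SSC": 300.0, "DAPI": 30.0, "PE": 10.0}
    events = pd.DataFrame([{**base, "FITC": v} for v in (1e4, 5e2, 10.0)])
    counts = classify_gfp(events)
    assert (counts.n_gfp_pos, counts.n_gfp_neg, counts.n_ambiguous) == (1, 1, 1)


def test_perfect_separation_classifies_without_error():
    events = _sample(
        LIVE_ONLY, seed=13, gfp_loss_rate=0.0,
        fitc_pos_log_sd=0.05, fitc_neg_log_sd=0.05,
    )
    gated, _ = apply_gates(events)
    counts = classify_gfp(gated)
    truth_pos = (gated["label"] == "gfp_pos").sum()
    assert counts.n_gfp_pos == truth_pos
    assert counts.n_ambiguous == 0


def test_balanced_mixture_recovered():
    gated, _ = apply_gates(_sample(LIVE_ONLY, n=40_000, seed=17))
    counts = classify_gfp(gated)
    n = counts.n_gfp_pos + counts.n_gfp_neg
    se = np.sqrt(0.25 / n)
    assert abs(counts.n_gfp_neg / n - 0.5) <= 3 * se + 0.005  # + GFP-loss drift


# ---------------------------------------------------------------------------
# growth ratios


def test_fraction_arithmetic():
    assert GFPCounts(5000, 5000, 0).fraction_gfp_neg == pytest.approx(0.5)
    with pytest.raises(ValueError):
        GFPCounts(0, 100, 0).fraction_gfp_neg


def test_growth_ratio_hand_example():
    """W_m=0.5, W_r=0.5, W_m*=0.1, W_r*=0.5 gives W_n=1, W_n*=0.2, ratio 0.2."""
    mk = lambda w, tot=10_000: GFPCounts(int(tot * (1 - w)), int(tot * w), 0)
    res = growth_ratio(mk(0.5), mk(0.1), mk(0.5), mk(0.5))
    assert res.w_n == pytest.approx(1.0)
    assert res.w_n_star == pytest.approx(0.2)
    assert res.growth_ratio == pytest.approx(0.2)


def test_identical_samples_give_unit_ratio():
    s = GFPCounts(4000, 3000, 10)
    res = growth_ratio(s, s, s, s)
    assert res.growth_ratio == pytest.approx(1.0)
    assert not res.below_detection


def test_swapping_mutant_and_reference_inverts_the_normalized_fraction():
    m = GFPCounts(6000, 3000, 0)
    r = GFPCounts(5000, 5000, 0)
    w_n = growth_ratio(m, m, r, r).w_n
    w_n_swapped = growth_ratio(r, r, m, m).w_n
    assert w_n_swapped == pytest.approx(1.0 / w_n)


def test_below_detection_flagged_not_clamped():
    mutant_treated = GFPCounts(10_000, 100, 0)  # count ratio 0.01 < 0.03
    res = growth_ratio(GFPCounts(5000, 5000, 0), mutant_treated, GFPCounts(5000, 5000, 0), GFPCounts(5000, 5000, 0))
    assert res.below_detection
    assert res.normalized_growth == pytest.approx(0.01)
    assert res.growth_ratio > 0  # value preserved, not truncated


def test_zero_gfp_positive_rejected():
    good = GFPCounts(5000, 5000, 0)
    with pytest.raises(ValueError):
        growth_ratio(GFPCounts(0, 100, 0), good, good, good)


# ---------------------------------------------------------------------------
# replicate statistics


def test_t_statistic_textbook_value():
    res = replicate_test([0.9, 1.0, 1.1], [0.4, 0.5, 0.6])
    assert res.t == pytest.approx(6.1237, abs=1e-3)
    assert res.df == 4


def test_identical_groups_and_degenerate_variance():
    assert replicate_test([1.0, 1.0, 1.0], [1.0, 1.0, 1.0]).p == 1.0
    res = replicate_test([0.9, 1.0, 1.1], [0.9, 1.0, 1.1])
    assert res.t == pytest.approx(0.0, abs=1e-12) and res.p == pytest.approx(1.0)


def test_welch_flag_changes_df():
    a, b = [0.9, 1.0, 1.1, 1.0], [0.2, 0.6, 0.4]
    assert replicate_test(a, b, welch=True).df != replicate_test(a, b, welch=False).df


# ---------------------------------------------------------------------------
# end-to-end invariance


def _gate_and_classify(events):
    gated, _ = apply_gates(events)
    return classify_gfp(gated)


def _competition_samples(rho, generations, n, seed, loss=0.002):
    """Four samples of a mutant-vs-reference competition (ref mutant rho=1)."""
    cfgs = {}
    for i, (name, r) in enumerate((("mu", 1.0), ("mt", rho), ("ru", 1.0), ("rt", 1.0))):
        cfgs[name] = FlowSimConfig(
            n_events=n,
            fractions=competition_fractions(r, generations),
            gfp_loss_rate=loss,
            seed=seed + 101 * i,
        )
    return {k: simulate_flow_events(c) for k, c in cfgs.items()}


def test_growth_ratio_recovers_closed_form():
    """Half-fitness mutant over 7 generations: ratio ~ 2/(1 + 2**3.5) within 5%."""
    samples = _competition_samples(rho=0.5, generations=7.0, n=100_000, seed=41)
    res = growth_ratio(*(_gate_and_classify(samples[k]) for k in ("mu", "mt", "ru", "rt")))
    expected = (1 / (1 + 2.0 ** ((1 - 0.5) * 7.0))) / 0.5
    assert res.growth_ratio == pytest.approx(expected, rel=0.05)


def test_growth_ratio_stable_under_subsampling():
    """50% random subsampling leaves the mean ratio within 2% of the full value."""
    samples = _competition_samples(rho=0.6, generations=7.0, n=20_000, seed=55)
    full = growth_ratio(*(_gate_and_classify(samples[k]) for k in ("mu", "mt", "ru", "rt")))
    rng = np.random.default_rng(123)
    ratios = []
    for _ in range(40):
        sub = {k: v.sample(frac=0.5, random_state=rng.integers(2**31 - 1)) for k, v in samples.items()}
        ratios.append(
            growth_ratio(*(_gate_and_classify(sub[k]) for k in ("mu", "mt", "ru", "rt"))).growth_ratio
        )
    assert np.mean(ratios) == pytest.approx(full.growth_ratio, rel=0.02)
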