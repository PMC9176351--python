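"""Training baselines, windowed fractions and the P_E ratio."""

from __future__ import annotations

import math

import numpy as np
import pytest

from cfgmon import (
    TrendSpec,
    annotate_stream,
    constant_trend,
    enrichment_trajectory,
    make_stream,
    odds_ratio,
    step_trend,
    training_profile,
    whole_run_enrichment,
    window_fractions,
)

ANILINE = "Nc1ccccc1"
METHANE = "C"
KETONE = "CC(C)=O"


def brute_force_fraction(records, group_name, start, end):
    """Independent recount: fraction of valid molecules in (start, end]."""
    window = records[start : end + 1]
    valid = [r for r in window if r.valid]
    return sum(r.group_flags[group_name] for r in valid) / len(valid)


def test_training_profile_hand_counts(annotate):
    records = annotate([ANILINE, METHANE, METHANE, METHANE])
    profile = training_profile(records, _catalog_of(records))
    assert profile.fractions["aniline"] == 0.25
    assert profile.fractions["azo"] == 0.0
    assert profile.n_training == 4


def _catalog_of(records):
    # the conftest annotate fixture always uses the default catalog
    from cfgmon import default_catalog

    return default_catalog()


def test_training_profile_excludes_invalid(annotate, catalog):
    records = annotate([ANILINE, "C1CC", METHANE])
    profile = training_profile(records, catalog)
    assert profile.n_training == 2
    assert profile.fractions["aniline"] == 0.5


def test_training_profile_needs_valid_molecules(annotate, catalog):
    with pytest.raises(ValueError, match="no valid"):
        training_profile(annotate(["C1CC", "notasmiles("]), catalog)


def test_window_fractions_hand_counts(annotate):
    records = annotate([KETONE, KETONE, METHANE, METHANE])
    p_f = window_fractions(records, window_length=4, window_end=3)
    assert p_f["ketone"] == 0.5
    p_f = window_fractions(records, window_length=2, window_end=1)
    assert p_f["ketone"] == 1.0


def test_window_fractions_outside_stream(annotate):
    records = annotate([METHANE] * 5)
    with pytest.raises(ValueError, match="not fully inside"):
        window_fractions(records, window_length=4, window_end=2)
    with pytest.raises(ValueError, match="not fully inside"):
        window_fractions(records, window_length=4, window_end=7)


def test_window_with_only_invalid_molecules_errors(annotate):
    records = annotate([KETONE, "C1CC", "C1CC", KETONE])
    with pytest.raises(ValueError, match="no valid"):
        window_fractions(records, window_length=2, window_end=2)


@pytest.mark.parametrize(
    "p_f, p_tf, expected",
    [
        # Enrichment of the printed run-level fraction pairs.
        (0.497, 0.766, 0.649),
        (0.00847, 0.0226, 0.375),
        (0.00878, 0.00371, 2.37),
        (0.000486, 0.00000619, 78.5),
        (0.1, 0.1, 1.0),
    ],
)
def test_odds_ratio_reference_values(p_f, p_tf, expected):
    value = odds_ratio(p_f, p_tf)
    assert float(f"{value:.3g}") == pytest.approx(expected)


def test_odds_ratio_zero_handling():
    with pytest.warns(RuntimeWarning, match="absent from training"):
        assert math.isinf(odds_ratio(0.2, 0.0))
    assert odds_ratio(0.0, 0.0) == 1.0
    assert odds_ratio(0.0, 0.3) == 0.0


def test_odds_ratio_pseudocount():
    assert odds_ratio(0.2, 0.0, pseudocount=0.1) == pytest.approx(3.0)
    assert odds_ratio(0.1, 0.1, pseudocount=0.05) == 1.0


@pytest.mark.parametrize("p_f, p_tf", [(-0.1, 0.5), (0.5, -0.1), (1.2, 0.5)])
def test_odds_ratio_rejects_bad_fractions(p_f, p_tf):
    with pytest.raises(ValueError):
        odds_ratio(p_f, p_tf)


def test_trajectory_single_window(annotate, catalog):
    records = annotate([KETONE, METHANE] * 5)
    profile = training_profile(records, catalog)
    traj = enrichment_trajectory(records, profile, catalog, window_length=10, stride=1)
    assert len(traj.points) == 1
    assert traj.points[0].window_end == 9
    assert traj.points[0].p_e["ketone"] == pytest.approx(1.0)


def test_trajectory_constant_stream_is_flat(annotate, catalog):
    records = annotate([KETONE] * 30)
    profile = training_profile(annotate([KETONE, METHANE]), catalog)
    traj = enrichment_trajectory(records, profile, catalog, window_length=10, stride=5)
    values = [pt.p_e["ketone"] for pt in traj.points]
    assert values == pytest.approx([2.0] * len(values))
    assert [pt.window_end for pt in traj.points] == [9, 14, 19, 24, 29]


def test_trajectory_matches_brute_force_recount(annotate, catalog):
    """Cumulative-count windowing equals a naive recount on every window."""
    rng = np.random.default_rng(42)
    pool = [KETONE, ANILINE, METHANE, "CN=NC", "C1CC", "CCO"]
    smiles = [pool[i] for i in rng.integers(0, len(pool), size=400)]
    records = annotate(smiles)
    profile = training_profile(annotate(pool[:4] + ["CCO"]), catalog)
    for window_length, stride in [(25, 1), (50, 7), (100, 100)]:
        traj = enrichment_trajectory(
            records, profile, catalog, window_length=window_length, stride=stride
        )
        for pt in traj.points:
            start = pt.window_end - window_length + 1
            for g in catalog.names:
                assert pt.p_f[g] == pytest.approx(
                    brute_force_fraction(records, g, start, pt.window_end)
                )


def test_trajectory_stream_shorter_than_window(annotate, catalog):
    records = annotate([KETONE] * 5)
    profile = training_profile(records, catalog)
    with pytest.raises(ValueError, match="shorter than window"):
        enrichment_trajectory(records, profile, catalog, window_length=10)


def test_step_change_detected_at_injected_ratio(catalog):
    """A 0.05 -> 0.5 step in quinone frequency lifts windowed P_E ~10x."""
    q = 0.05
    trend = TrendSpec("1,4-quinone", step_trend(q, 0.5, 500))
    smiles, _ = make_stream([trend], 1000, seed=7)
    records = annotate_stream(smiles, catalog)
    train = annotate_stream(
        make_training_smiles(q, seed=11), catalog
    )
    profile = training_profile(train, catalog)
    traj = enrichment_trajectory(records, profile, catalog, window_length=100, stride=50)
    before = [pt.p_e["1,4-quinone"] for pt in traj.points if pt.window_end < 500]
    after = [pt.p_e["1,4-quinone"] for pt in traj.points if pt.window_end >= 700]
    assert np.mean(after) / np.mean(before) == pytest.approx(10.0, rel=0.5)


def make_training_smiles(q, seed, n=2000):
    from cfgmon import make_training_set

    return make_training_set({"1,4-quinone": q}, n=n, seed=seed)


def test_whole_run_identity_on_training_set(annotate, catalog):
    records = annotate([KETONE, ANILINE, METHANE, "CN=NC"])
    profile = training_profile(records, catalog)
    p_e = whole_run_enrichment(records, profile, catalog)
    for g, value in p_e.items():
        if profile.fractions[g] > 0:
            assert value == pytest.approx(1.0)
        else:
            assert value == 1.0  # 0/0 convention


def test_whole_run_hand_built_counts(annotate, catalog):
    # 20 molecules: 5 ketone, 4 aniline, 11 inert; training 1/2 ketone, 1/4 aniline.
    stream = annotate([KETONE] * 5 + [ANILINE] * 4 + [METHANE] * 11)
    train = annotate([KETONE, KETONE, ANILINE, METHANE])
    profile = training_profile(train, catalog)
    p_e = whole_run_enrichment(stream, profile, catalog)
    assert p_e["ketone"] == pytest.approx((5 / 20) / (2 / 4))
    assert p_e["aniline"] == pytest.approx((4 / 20) / (1 / 4))


def test_whole_run_absent_group_is_zero(annotate, catalog):
    stream = annotate([METHANE] * 10)
    profile = training_profile(annotate([ANILINE, METHANE]), catalog)
    assert whole_run_enrichment(stream, profile, catalog)["aniline"] == 0.0


def test_whole_run_empty_stream(annotate, catalog):
    profile = training_profile(annotate([METHANE]), catalog)
    with pytest.raises(ValueError, match="empty"):
        whole_run_enrichment([], profile, catalog)


def test_duplication_invariance(annotate, catalog):
    """Repeating every stream molecule k times changes no fraction."""
    base = [KETONE, ANILINE, METHANE, "CN=NC", "CCO"]
    profile = training_profile(annotate(base), catalog)
    single = annotate(base)
    tripled = annotate([s for s in base for _ in range(3)])
    p_e_single = whole_run_enrichment(single, profile, catalog)
    p_e_tripled = whole_run_enrichment(tripled, profile, catalog)
    for g in catalog.names:
        assert p_e_single[g] == pytest.approx(p_e_tripled[g])


def test_monotonicity_in_matching_count(annotate, catalog):
    """More matching molecules in a fixed-size window never lowers P_f."""
    profile = training_profile(annotate([KETONE, METHANE]), catalog)
    previous = -1.0
    for k in range(0, 11):
        records = annotate([KETONE] * k + [METHANE] * (10 - k))
        p_f = window_fractions(records, 10, 9)["ketone"]
        assert p_f >= previous
        previous = p_f


def test_binomial_error_shrinks_with_window_length(catalog):
    """P_E estimates concentrate around p/q as the window grows."""
    q, p = 0.1, 0.3
    smiles, _ = make_stream([TrendSpec("azo", constant_trend(p))], 4000, seed=3)
    records = annotate_stream(smiles, catalog)
    train = annotate_stream(
        __import__("cfgmon").make_training_set({"azo": q}, n=5000, seed=5), catalog
    )
    profile = training_profile(train, catalog)
    target = p / profile.fractions["azo"]
    spreads = {}
    for window in (100, 1000):
        traj = enrichment_trajectory(records, profile, catalog, window_length=window, stride=window)
        values = np.array([pt.p_e["azo"] for pt in traj.points])
        spreads[window] = np.sqrt(np.mean((values - target) ** 2))
    assert spreads[1000] < spreads[100]
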