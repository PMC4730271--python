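import numpy as np
import pytest

from nucdisorder.disorder_metrics import DisorderProfile
from nucdisorder.enrichment_stats import (
    METRICS,
    ComparisonResult,
    StatsConfig,
    choose_test,
    compare,
    compare_groups,
    matched_control_sample,
    repeat_measure,
    results_to_frame,
    run_all_comparisons,
)
from nucdisorder.data_io import ProteinRecord, assemble_datasets


def _profile(pid, length=100, content=0.1, n_domains=0):
    return DisorderProfile(pid, length, content, (30,) * n_domains)


def _pool(rng, n=200, content_mean=0.15):
    return [
        _profile(f"C{i}", int(rng.integers(50, 1000)), float(np.clip(rng.normal(content_mean, 0.1), 0, 1)))
        for i in range(n)
    ]


def test_matched_control_length_window():
    # L=100 with 10% tolerance admits [90, 110]: 111 and 200 are excluded
    targets = [_profile("T", length=100)]
    pool = [_profile("A", 90), _profile("B", 111), _profile("C", 200)]
    rng = np.random.default_rng(0)
    for _ in range(10):
        chosen = matched_control_sample(targets, pool, 0.10, rng)
        assert [c.length for c in chosen] == [90]


def test_matched_control_degenerate_tolerance():
    targets = [_profile("T", length=100)]
    pool = [_profile("A", 5000)]
    chosen = matched_control_sample(targets, pool, 1.0, np.random.default_rng(0))
    # tolerance 1.0 admits [0, 2L]; 5000 is outside, so the nearest-length
    # fallback fires and still returns a control
    assert len(chosen) == 1


def test_matched_control_without_replacement_and_fallback():
    targets = [_profile(f"T{i}", length=100) for i in range(3)]
    pool = [_profile("A", 100), _profile("B", 101), _profile("C", 400)]
    chosen = matched_control_sample(targets, pool, 0.10, np.random.default_rng(1))
    assert sorted(c.protein_id for c in chosen) == ["A", "B", "C"]  # no duplicates


def test_matched_control_pool_too_small():
    with pytest.raises(ValueError, match="pool"):
        matched_control_sample(
            [_profile("T1"), _profile("T2")], [_profile("A")], 0.1,
            np.random.default_rng(0),
        )


def test_matched_control_deterministic_under_seed():
    rng1 = np.random.default_rng(42)
    rng2 = np.random.default_rng(42)
    targets = [_profile(f"T{i}", length=int(l)) for i, l in enumerate([100, 300, 700])]
    pool = _pool(np.random.default_rng(9))
    a = matched_control_sample(targets, pool, 0.1, rng1)
    b = matched_control_sample(targets, pool, 0.1, rng2)
    assert [p.protein_id for p in a] == [p.protein_id for p in b]


def test_repeat_measure_set_size_metric():
    cfg = StatsConfig()
    targets = [_profile(f"T{i}") for i in range(9)]
    pool = _pool(np.random.default_rng(3))
    v1, v2 = repeat_measure(len, targets, pool, cfg, np.random.default_rng(0))
    assert v1.tolist() == [5.0] * 10  # ceil(9/2)
    assert v2.tolist() == [5.0] * 10


def test_repeat_measure_needs_two_targets():
    with pytest.raises(ValueError):
        repeat_measure(
            len, [_profile("T")], _pool(np.random.default_rng(3)),
            StatsConfig(), np.random.default_rng(0),
        )


def test_choose_test_paths():
    rng = np.random.default_rng(11)
    normal1 = rng.normal(0, 1, 20)
    normal2 = rng.normal(0, 1, 20)
    assert choose_test(normal1, normal2) == "t"
    skewed = np.exp(rng.normal(0, 2, 20)) ** 2
    assert choose_test(normal1, skewed) == "wilcoxon"
    assert choose_test(np.ones(10), normal2) == "wilcoxon"
    with pytest.raises(ValueError):
        choose_test(np.array([1.0, 2.0]), normal2)


def test_compare_identical_vectors_not_significant():
    v = np.arange(10, dtype=float)
    res = compare(v, v.copy(), StatsConfig())
    assert res.p_value == 1.0
    assert res.direction == "="


def test_compare_large_shift_positive():
    rng = np.random.default_rng(2)
    v2 = rng.normal(0, 1, 10)
    res = compare(v2 + 100.0, v2, StatsConfig())
    assert res.direction == "+"
    assert res.p_value < 0.01


def test_degenerate_alpha_makes_everything_significant():
    rng = np.random.default_rng(4)
    cfg = StatsConfig(alpha_sig=1.0)
    v1 = rng.normal(0.1, 1, 10)
    v2 = rng.normal(0.0, 1, 10)
    res = compare(v1, v2, cfg)
    assert res.direction in "+-"  # sign check only


def _toy_study(rng, n_comp=40, n_pool=300, shift=0.0):
    records, comp_map = [], {}
    for i in range(n_pool):
        records.append(ProteinRecord(f"C{i}", "M" * int(rng.integers(50, 500))))
    for i in range(n_comp):
        pid = f"N{i}"
        records.append(ProteinRecord(pid, "M" * int(rng.integers(50, 500))))
        comp_map[pid] = (frozenset({"nucleolus"}), "annotated")
    ds = assemble_datasets(records, comp_map)
    profiles = {}
    for rec in records:
        base = 0.2 + (shift if rec.protein_id.startswith("N") else 0.0)
        content = float(np.clip(rng.normal(base, 0.08), 0, 1))
        profiles[rec.protein_id] = DisorderProfile(
            rec.protein_id, rec.length, content, (30,) * int(rng.poisson(1))
        )
    return ds, profiles


def test_run_all_comparisons_deterministic_under_seed():
    ds, profiles = _toy_study(np.random.default_rng(8))
    cfg = StatsConfig(seed=77)
    a = results_to_frame(run_all_comparisons(ds, profiles, cfg))
    b = results_to_frame(run_all_comparisons(ds, profiles, cfg))
    assert a.equals(b)


def test_run_all_comparisons_skips_small_compartments(caplog):
    ds, profiles = _toy_study(np.random.default_rng(8), n_comp=3)
    results = run_all_comparisons(ds, profiles, StatsConfig(seed=1))
    assert results == []


def test_programmed_shift_detected_in_both_units():
    for unit in ("protein", "subset"):
        ds, profiles = _toy_study(np.random.default_rng(10), shift=0.2)
        cfg = StatsConfig(seed=5, sample_unit=unit)
        results = run_all_comparisons(ds, profiles, cfg, metrics=("median_content",))
        assert len(results) == 1
        assert results[0].direction == "+"


def test_power_nondecreasing_in_effect_size():
    call_rates = []
    for shift in (0.0, 0.1, 0.3):
        plus = 0
        for rep in range(10):
            ds, profiles = _toy_study(
                np.random.default_rng(100 + rep), n_comp=30, shift=shift
            )
            res = run_all_comparisons(
                ds, profiles, StatsConfig(seed=rep), metrics=("mean_content",)
            )
            plus += res[0].direction == "+"
        call_rates.append(plus / 10)
    assert call_rates[0] <= call_rates[1] <= call_rates[2]
    assert call_rates[2] == 1.0


def test_metric_registry_consistency():
    # the set-level value of each fraction metric equals the mean of its
    # per-protein indicator, scaled to percent
    rng = np.random.default_rng(19)
    profiles = [
        _profile(f"P{i}", int(rng.integers(50, 500)), float(rng.random()),
                 int(rng.integers(0, 7)))
        for i in range(40)
    ]
    for name in ("pct_disprot", "pct_disdomprot", "pct_3plus", "pct_5plus"):
        spec = METRICS[name]
        assert spec["set_fn"](profiles) == pytest.approx(
            100 * np.mean([spec["protein_fn"](p) for p in profiles])
        )
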