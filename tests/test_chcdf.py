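import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nucdisorder.chcdf import (
    CDFBoundary,
    CHBoundary,
    cdf_curve,
    cdf_distance,
    ch_coordinates,
    ch_distance,
    chcdf_point,
    classify_quadrant,
    load_boundaries,
    quadrant_fractions,
)

# published Kyte-Doolittle hydropathy values, restated for the oracle below
KD = {
    "I": 4.5, "V": 4.2, "L": 3.8, "F": 2.8, "C": 2.5, "M": 1.9, "A": 1.8,
    "G": -0.4, "T": -0.7, "S": -0.8, "W": -0.9, "Y": -1.3, "P": -1.6,
    "H": -3.2, "E": -3.5, "Q": -3.5, "D": -3.5, "N": -3.5, "K": -3.9, "R": -4.5,
}

FIXTURE_CH = CHBoundary(slope=2.785, intercept=-1.151)
FIXTURE_CDF = CDFBoundary(points=tuple((t, 0.1 + t / 2) for t in (0.2, 0.4, 0.6, 0.8)))


def _ch_oracle(seq, window=5):
    """Hand computation: rescale, smooth with truncated windows, average."""
    vals = [(KD.get(a, 0.0) + 4.5) / 9.0 for a in seq]
    smoothed = []
    half = window // 2
    for i in range(len(seq)):
        lo, hi = max(0, i - half), min(len(seq), i + half + 1)
        smoothed.append(sum(vals[lo:hi]) / (hi - lo))
    charge = sum({"D": -1, "E": -1, "K": 1, "R": 1}.get(a, 0) for a in seq)
    return sum(smoothed) / len(seq), abs(charge) / len(seq)


def test_polyglycine_has_zero_net_charge():
    _, charge = ch_coordinates("G" * 100)
    assert charge == 0.0


def test_polylysine_charge_is_one():
    _, charge = ch_coordinates("K" * 100)
    assert charge == 1.0


def test_mixed_sequence_matches_table_lookup_oracle():
    rng = np.random.default_rng(5)
    aas = list(KD)
    for _ in range(20):
        seq = "".join(rng.choice(aas, size=50))
        h, q = ch_coordinates(seq)
        oh, oq = _ch_oracle(seq)
        assert h == pytest.approx(oh)
        assert q == pytest.approx(oq)


def test_x_residue_contributes_midpoint_and_zero_charge():
    h, q = ch_coordinates("X" * 10)
    assert h == pytest.approx(0.5)
    assert q == 0.0


def test_ch_distance_zero_on_the_line():
    # pick a sequence, then a boundary passing exactly through it
    seq = "MKRE" * 10
    h, q = ch_coordinates(seq)
    boundary = CHBoundary(slope=1.0, intercept=q - h)
    assert ch_distance(seq, boundary) == pytest.approx(0.0)


def test_polylysine_is_above_default_boundary():
    assert ch_distance("K" * 100, FIXTURE_CH) > 0


def test_more_hydropathy_decreases_ch_distance():
    # replacing glycine with isoleucine raises hydropathy at fixed charge
    seqs = ["K" * 10 + "G" * 40, "K" * 10 + "G" * 20 + "I" * 20, "K" * 10 + "I" * 40]
    ys = [ch_distance(s, FIXTURE_CH) for s in seqs]
    assert ys[0] > ys[1] > ys[2]


def test_cdf_curve_degenerate_scores():
    thr = FIXTURE_CDF.thresholds
    assert cdf_curve(np.zeros(30), thr).tolist() == [1.0] * len(thr)
    assert cdf_curve(np.ones(30), thr).tolist() == [0.0] * len(thr)


def test_cdf_curve_matches_direct_count():
    rng = np.random.default_rng(6)
    for _ in range(200):
        scores = rng.random(rng.integers(1, 60))
        thr = np.sort(rng.random(5))
        curve = cdf_curve(scores, thr)
        for t, c in zip(thr, curve):
            assert c == pytest.approx(sum(s <= t for s in scores) / len(scores))


def test_cdf_curve_monotone_and_raised_by_zero_scores():
    rng = np.random.default_rng(13)
    thr = FIXTURE_CDF.thresholds
    scores = rng.random(40)
    curve = cdf_curve(scores, thr)
    assert np.all(np.diff(curve) >= 0)
    longer = cdf_curve(np.append(scores, 0.0), thr)
    assert np.all(longer >= curve)


def test_cdf_distance_examples():
    b = FIXTURE_CDF
    assert cdf_distance(b.fractions, b) == pytest.approx(0.0)
    assert cdf_distance(b.fractions + 0.1, b) == pytest.approx(0.1)
    with pytest.raises(ValueError):
        cdf_distance(b.fractions[:-1], b)


@pytest.mark.parametrize(
    "x, y, quadrant",
    [
        (0.1, 0.1, "Q1"),
        (0.1, -0.1, "Q2"),
        (-0.1, -0.1, "Q3"),
        (-0.1, 0.1, "Q4"),
        (0.0, 0.0, "Q2"),   # boundary points go to the ordered side
        (0.0, 0.1, "Q1"),
        (0.1, 0.0, "Q2"),
    ],
)
def test_quadrant_classification(x, y, quadrant):
    assert classify_quadrant(x, y) == quadrant


def test_quadrant_rejects_non_finite():
    with pytest.raises(ValueError):
        classify_quadrant(float("nan"), 0.0)


@given(
    st.floats(-1, 1, allow_nan=False),
    st.floats(-1, 1, allow_nan=False),
)
def test_quadrants_partition_the_plane(x, y):
    assert classify_quadrant(x, y) in {"Q1", "Q2", "Q3", "Q4"}


def test_quadrant_fractions_sum_to_100():
    pts = [
        chcdf_point(f"P{i}", seq, scores, FIXTURE_CH, FIXTURE_CDF)
        for i, (seq, scores) in enumerate(
            [
                ("K" * 60, np.full(60, 0.9)),
                ("I" * 60, np.full(60, 0.1)),
                ("IKGS" * 15, np.full(60, 0.5)),
                ("G" * 60, np.full(60, 0.99)),
            ]
        )
    ]
    frac = quadrant_fractions(pts)
    assert frac["Q1"] + frac["Q2"] + frac["Q3"] + frac["Q4"] == pytest.approx(100.0)
    assert frac["Q3+Q4"] == pytest.approx(frac["Q3"] + frac["Q4"])


def test_quadrant_fractions_examples():
    mk = lambda q, i: type("P", (), {"quadrant": q, "protein_id": str(i)})()
    frac = quadrant_fractions([mk("Q1", 0), mk("Q2", 1), mk("Q3", 2), mk("Q4", 3)])
    assert [frac[q] for q in ("Q1", "Q2", "Q3", "Q4")] == [25.0] * 4
    frac = quadrant_fractions([mk("Q2", i) for i in range(5)])
    assert frac["Q2"] == 100.0 and frac["Q4"] == 0.0
    with pytest.raises(ValueError):
        quadrant_fractions([])


def test_quadrant_fractions_match_programmed_signs():
    rng = np.random.default_rng(30)
    pts = []
    truth = {"Q1": 0, "Q2": 0, "Q3": 0, "Q4": 0}
    for i in range(200):
        x = float(rng.uniform(-1, 1)) or 0.5
        y = float(rng.uniform(-1, 1)) or 0.5
        q = ("Q1" if y > 0 else "Q2") if x >= 0 else ("Q4" if y > 0 else "Q3")
        truth[q] += 1
        pts.append(type("P", (), {"quadrant": classify_quadrant(x, y), "protein_id": str(i)})())
    frac = quadrant_fractions(pts)
    for q, n in truth.items():
        assert frac[q] == pytest.approx(100 * n / 200)


def test_default_boundary_config_loads():
    ch, cdf = load_boundaries()
    assert ch.slope > 0
    assert len(cdf.points) >= 2
    assert np.all(np.diff(cdf.thresholds) > 0)


def test_boundary_validation():
    with pytest.raises(ValueError):
        CHBoundary(slope=-1.0, intercept=0.0)
    with pytest.raises(ValueError):
        CDFBoundary(points=((0.5, 0.5),))
    with pytest.raises(ValueError):
        CDFBoundary(points=((0.5, 0.5), (0.5, 0.6)))
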