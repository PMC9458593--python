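"""SRIA measurement: channel extraction, thresholding, pixel counting,
inclusion rule and IF-grade translation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from shapely.geometry import Point, box

from sriaquant import (
    check_pair_inclusion,
    compute_sria,
    extract_collagen_channel,
    map_to_remuzzi,
    quantify_pair,
    quantify_section,
    select_threshold,
)
from sriaquant.quantify import (
    PICRIC_YELLOW_RGB,
    SIRIUS_RED_RGB,
    BiopsyPair,
    SriaMeasurement,
    rasterize_geometry,
)

from conftest import make_flat_section


def _solid(rgb, shape=(4, 4)):
    return np.tile(np.asarray(rgb, dtype=np.uint8), (*shape, 1))


@pytest.mark.parametrize("method", ["deconvolution", "hue_saturation"])
def test_channel_white_is_unstained_and_red_beats_yellow(method):
    white = extract_collagen_channel(_solid((255, 255, 255)), method)
    assert np.all(white < 0.02)
    red = extract_collagen_channel(_solid(SIRIUS_RED_RGB), method)
    yellow = extract_collagen_channel(_solid(PICRIC_YELLOW_RGB), method)
    assert np.all(red > yellow)


def test_channel_black_image_defined_and_zero():
    black = extract_collagen_channel(_solid((0, 0, 0)), "deconvolution")
    assert np.all(black == 0.0)


def test_channel_unknown_method_raises():
    with pytest.raises(ValueError, match="method"):
        extract_collagen_channel(_solid((10, 10, 10)), "magic")


@pytest.mark.parametrize("method", ["deconvolution", "hue_saturation"])
def test_channel_separates_ground_truth_collagen(section_pair_small, method):
    """Channel ranking separates true collagen from background (AUC > 0.99)."""
    from scipy.stats import rankdata

    _, _, paraffin, _, truth_p = section_pair_small
    eff = truth_p.effective_mask()
    labels = truth_p.collagen_mask[eff]
    values = extract_collagen_channel(paraffin, method)[eff]
    ranks = rankdata(values)
    n1, n0 = labels.sum(), (~labels).sum()
    auc = (ranks[labels].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    assert auc > 0.99


def test_otsu_bisects_two_level_image():
    channel = np.array([0.0] * 50 + [1.0] * 50)
    thr = select_threshold(channel, np.ones(100, dtype=bool), "otsu")
    assert 0.0 < thr < 1.0


def test_otsu_lands_between_bimodal_modes():
    rng = np.random.default_rng(0)
    channel = np.concatenate([
        rng.normal(0.2, 0.02, 500), rng.normal(0.8, 0.02, 500)
    ]).clip(0, 1)
    thr = select_threshold(channel, np.ones(1000, dtype=bool), "otsu")
    assert 0.2 < thr < 0.8


def test_fixed_threshold_is_identity_and_constant_otsu_errors():
    assert select_threshold(np.zeros(9), np.ones(9, bool), "fixed", 0.5) == 0.5
    with pytest.raises(ValueError, match="fixed_value"):
        select_threshold(np.full(9, 0.3), np.ones(9, bool), "otsu")


def test_half_stained_cortex_is_fifty_percent():
    img = make_flat_section(shape=(100, 100))
    channel = np.zeros((100, 100))
    channel[:50] = 0.9  # 5000 of 10000 pixels above threshold
    m = compute_sria(channel, 0.5, img)
    assert m.cortex_px == 10_000
    assert m.fraction_pct == 50.0


def test_exclusion_covering_all_stained_pixels_gives_zero():
    stained_region = box(-0.5, -0.5, 99.5, 49.5)  # rows 0..49
    img = make_flat_section(shape=(100, 100),
                            exclusions=[("fold", stained_region)])
    channel = np.zeros((100, 100))
    channel[:50] = 0.9
    m = compute_sria(channel, 0.5, img)
    assert m.fraction_pct == 0.0


def test_exclusions_shift_fraction_in_the_documented_direction():
    channel = np.zeros((100, 100))
    channel[:50] = 0.9
    base = compute_sria(channel, 0.5, make_flat_section(shape=(100, 100)))
    unstained_excl = make_flat_section(
        shape=(100, 100), exclusions=[("glomerulus", box(9.5, 59.5, 39.5, 89.5))]
    )
    stained_excl = make_flat_section(
        shape=(100, 100), exclusions=[("vessel", box(9.5, 9.5, 39.5, 39.5))]
    )
    assert compute_sria(channel, 0.5, unstained_excl).fraction_pct > base.fraction_pct
    assert compute_sria(channel, 0.5, stained_excl).fraction_pct < base.fraction_pct


def test_compute_sria_matches_brute_force_pixel_oracle():
    """Fraction equals an independent per-pixel double loop with shapely
    point-in-polygon tests."""
    rng = np.random.default_rng(11)
    h = w = 24
    cortex = Point(11.3, 11.7).buffer(9.2, quad_segs=6)
    excl = box(5.2, 4.8, 9.9, 9.1)
    img = make_flat_section(shape=(h, w), mpp=25.0, cortex=cortex,
                            exclusions=[("glomerulus", excl)])
    channel = rng.random((h, w))
    thr = 0.6
    m = compute_sria(channel, thr, img)

    stained = cortex_n = 0
    for r in range(h):
        for c in range(w):
            p = Point(c, r)
            if cortex.contains(p) and not excl.contains(p):
                cortex_n += 1
                if channel[r, c] >= thr:
                    stained += 1
    assert m.cortex_px == cortex_n
    assert m.stained_px == stained
    assert m.fraction_pct == 100.0 * stained / cortex_n
    assert m.analysed_area_mm2 == cortex_n * 25.0**2 / 1e6


def test_empty_effective_cortex_raises():
    img = make_flat_section(
        shape=(20, 20), exclusions=[("fold", box(-1, -1, 20, 20))]
    )
    with pytest.raises(ValueError, match="empty effective cortex"):
        compute_sria(np.zeros((20, 20)), 0.5, img)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(st.floats(0.0, 1.0), st.floats(0.0, 1.0))
def test_lower_threshold_never_decreases_stained_fraction(t1, t2):
    rng = np.random.default_rng(5)
    channel = rng.random((30, 30))
    img = make_flat_section(shape=(30, 30))
    lo, hi = sorted((t1, t2))
    m_lo = compute_sria(channel, lo, img)
    m_hi = compute_sria(channel, hi, img)
    assert m_lo.stained_px >= m_hi.stained_px
    assert m_lo.fraction_pct >= m_hi.fraction_pct


def _measurement(biopsy_id, kind, area_mm2, mpp=1.0):
    cortex_px = int(round(area_mm2 * 1e6 / mpp**2))
    return SriaMeasurement(
        stained_px=0, cortex_px=cortex_px, fraction_pct=0.0, threshold=0.5,
        analysed_area_mm2=cortex_px * mpp**2 / 1e6, channel_method="deconvolution",
        biopsy_id=biopsy_id, section_kind=kind,
    )


@pytest.mark.parametrize(
    "area_f, area_p, expect_included",
    [
        (0.9, 2.0, False),   # smaller member below the 1 mm² rule
        (1.0, 1.0, True),    # boundary is inclusive
        (4.194304, 4.194304, True),  # 2048x2048 px at 1 µm/px, fully cortex
    ],
)
def test_minimum_area_inclusion_rule(area_f, area_p, expect_included):
    pair = BiopsyPair(
        frozen=_measurement("b1", "frozen", area_f),
        paraffin=_measurement("b1", "paraffin", area_p),
    )
    checked = check_pair_inclusion(pair, min_area_mm2=1.0)
    assert checked.included is expect_included
    if not expect_included:
        assert "below 1 mm²" in checked.exclusion_reason


def test_pair_identity_and_kind_validation():
    with pytest.raises(ValueError, match="biopsy_id"):
        BiopsyPair(frozen=_measurement("b1", "frozen", 1.0),
                   paraffin=_measurement("b2", "paraffin", 1.0))
    with pytest.raises(ValueError, match="section kinds"):
        BiopsyPair(frozen=_measurement("b1", "paraffin", 1.0),
                   paraffin=_measurement("b1", "frozen", 1.0))


@pytest.mark.parametrize(
    "fraction, grade",
    [(0.0, 0), (4.99, 0), (5.0, 1), (19.9, 1), (20.0, 2), (32.0, 2),
     (49.9, 2), (50.0, 3), (55.0, 3), (100.0, 3)],
)
def test_remuzzi_grade_bins(fraction, grade):
    assert map_to_remuzzi(fraction).grade == grade


def test_remuzzi_invalid_cutpoints_raise():
    for cuts in [(20, 5, 50), (5, 5, 50), (0, 20, 50), (5, 20, 100)]:
        with pytest.raises(ValueError):
            map_to_remuzzi(10.0, cuts)


@settings(derandomize=True, max_examples=60, deadline=None)
@given(st.floats(0.0, 100.0, allow_nan=False))
def test_remuzzi_mapping_total_and_monotone(fraction):
    grade = map_to_remuzzi(fraction).grade
    assert grade in (0, 1, 2, 3)
    if fraction >= 1.0:
        assert map_to_remuzzi(fraction - 1.0).grade <= grade


def test_measured_sria_matches_ground_truth(section_pair_small):
    """End of the measurement chain: artefact-free paraffin recovery and
    frozen inflation both track the emitted ground truth within 2 pp."""
    _, frozen, paraffin, truth_f, truth_p = section_pair_small
    pair = quantify_pair(frozen, paraffin)
    assert pair.paraffin.fraction_pct == pytest.approx(
        truth_p.realised_fraction_pct, abs=2.0
    )
    assert pair.frozen.fraction_pct == pytest.approx(
        truth_f.realised_fraction_pct, abs=2.0
    )


def test_rasterize_uses_pixel_centre_convention():
    # box covering centres (0..2, 0..2) exactly: 3x3 pixels
    mask = rasterize_geometry(box(-0.5, -0.5, 2.5, 2.5), (5, 5))
    assert mask[:3, :3].all() and mask.sum() == 9
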