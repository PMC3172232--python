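import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from painmvpa.atlas import make_atlas, mni_like_affine
from painmvpa.design import make_design
from painmvpa.extraction import (
    ExampleMap,
    ExtractionError,
    FeatureMask,
    build_feature_mask,
    extract_psc_map,
    extract_subject_examples,
    smooth_volume,
    vectorize_examples,
    window_frames,
)
from painmvpa.simulate import BoldRun, simulate_subject


def _flat_run(value=1000.0, shape=(8, 8, 8), n_frames=245, tr=2.0, events=None):
    vol = np.full(shape + (n_frames,), value)
    return BoldRun(
        volume4d=vol,
        affine=mni_like_affine(shape, 4.0),
        tr_seconds=tr,
        events=events or [(40.0, 30.0, "painful")],
        condition="painful",
        run_id="run-01",
    )


# ---------------------------------------------------------------- smoothing


def test_zero_fwhm_is_identity():
    run = _flat_run()
    assert smooth_volume(run, 0.0) is run


def test_constant_frame_unchanged_by_smoothing():
    run = smooth_volume(_flat_run(value=123.0), 4.0)
    assert np.allclose(run.volume4d, 123.0)


def test_delta_frame_spreads_like_a_gaussian_kernel():
    shape = (17, 17, 17)
    vol = np.zeros(shape + (1,))
    vol[8, 8, 8, 0] = 1.0
    run = BoldRun(vol, mni_like_affine(shape, 4.0), 2.0, [], "painful")
    out = smooth_volume(run, 4.0).volume4d[..., 0]
    # independent oracle: the discrete truncated-Gaussian center weight
    sigma_vox = (4.0 / (2 * np.sqrt(2 * np.log(2)))) / 4.0
    radius = int(4.0 * sigma_vox + 0.5)
    w = np.exp(-0.5 * (np.arange(-radius, radius + 1) / sigma_vox) ** 2)
    w /= w.sum()
    center_weight = w[radius] ** 3
    assert out[8, 8, 8] == pytest.approx(center_weight, rel=1e-12)
    assert out.sum() == pytest.approx(1.0, abs=1e-6)


def test_negative_fwhm_rejected():
    with pytest.raises(ExtractionError):
        smooth_volume(_flat_run(), -1.0)


# --------------------------------------------------------------- psc windows


def test_window_frame_counts_at_tr2():
    run = _flat_run()
    assert window_frames(run, 20.0, 40.0).size == 10   # baseline
    assert window_frames(run, 46.0, 70.0).size == 12   # stimulus


@pytest.mark.parametrize("tr,base_n,stim_n", [(1.0, 20, 24), (2.0, 10, 12)])
def test_window_counts_follow_tr_not_seconds(tr, base_n, stim_n):
    n = int(490 / tr)
    run = _flat_run(n_frames=n, tr=tr)
    assert window_frames(run, 20.0, 40.0).size == base_n
    assert window_frames(run, 46.0, 70.0).size == stim_n


def test_psc_formula_on_step_signal():
    run = _flat_run()
    frames = np.arange(245) * 2.0
    stim = (frames >= 46.0) & (frames < 70.0)
    run.volume4d[..., stim] = 1010.0
    example = extract_psc_map(run, run.events[0])
    assert np.allclose(example.psc, 1.0)
    assert example.label == 1


def test_psc_zero_when_baseline_equals_stimulus():
    example = extract_psc_map(_flat_run(), (40.0, 30.0, "nonpainful"))
    assert np.allclose(example.psc, 0.0)
    assert example.label == -1


def test_zero_baseline_yields_nan_and_report(caplog):
    run = _flat_run(value=0.0)
    run.volume4d += 0.0
    with caplog.at_level("WARNING"):
        example = extract_psc_map(run, run.events[0])
    assert np.isnan(example.psc).all()
    assert "zero baseline" in caplog.text


def test_out_of_range_event_names_the_event():
    run = _flat_run()
    with pytest.raises(ExtractionError, match="onset=10"):
        extract_psc_map(run, (10.0, 30.0, "painful"))
    with pytest.raises(ExtractionError, match="onset=480"):
        extract_psc_map(run, (480.0, 30.0, "painful"))


def test_extraction_is_linear_in_signal_deviation():
    rng = np.random.default_rng(0)
    base = _flat_run()
    dev = rng.normal(0, 5.0, size=base.volume4d.shape)
    run1 = _flat_run()
    run1.volume4d = 1000.0 + dev
    run2 = _flat_run()
    run2.volume4d = 1000.0 + 3.0 * dev
    psc1 = extract_psc_map(run1, run1.events[0]).psc
    psc2 = extract_psc_map(run2, run2.events[0]).psc
    # with a common baseline level, tripling the deviation triples the
    # numerator while the denominator moves with it: check the exact identity
    b1 = run1.volume4d[..., window_frames(run1, 20, 40)].mean(-1)
    b2 = run2.volume4d[..., window_frames(run2, 20, 40)].mean(-1)
    assert np.allclose(psc2 * b2, 3.0 * psc1 * b1)


# ------------------------------------------------------------- feature mask


def _example(psc, label=1, sid="s1"):
    return ExampleMap(psc=psc, subject_id=sid, run_id="run-01", stimulus_index=0, label=label)


def test_mask_without_artifacts_equals_gray_count():
    gray = np.zeros((6, 6, 6), bool)
    gray[1:5, 1:5, 1:5] = True
    examples = [_example(np.zeros((6, 6, 6)))]
    mask = build_feature_mask(gray, examples)
    assert mask.n_features == gray.sum()


def test_single_large_psc_excludes_voxel():
    gray = np.ones((4, 4, 4), bool)
    psc = np.zeros((4, 4, 4))
    psc[2, 2, 2] = 5.0
    mask = build_feature_mask(gray, [_example(psc), _example(np.zeros((4, 4, 4)))])
    assert not mask.include[2, 2, 2]
    assert mask.n_features == 63


def test_infinite_threshold_reduces_to_gray_mask():
    gray = np.ones((4, 4, 4), bool)
    psc = np.full((4, 4, 4), 50.0)
    mask = build_feature_mask(gray, [_example(psc)], threshold_percent=np.inf)
    assert np.array_equal(mask.include, gray)


def test_empty_mask_is_an_error():
    gray = np.ones((3, 3, 3), bool)
    with pytest.raises(ExtractionError, match="empty"):
        build_feature_mask(gray, [_example(np.full((3, 3, 3), 9.0))])


@given(st.floats(0.5, 10.0), st.floats(0.0, 5.0))
@settings(max_examples=25, deadline=None)
def test_raising_threshold_never_removes_voxels(threshold, extra):
    gray = np.ones((4, 4, 4), bool)
    rng = np.random.default_rng(7)
    psc = rng.normal(0, 2.0, size=(4, 4, 4))
    examples = [_example(psc)]
    lo = build_feature_mask(gray, examples, threshold_percent=threshold)
    hi = build_feature_mask(gray, examples, threshold_percent=threshold + extra)
    assert np.all(hi.include >= lo.include)


# ---------------------------------------------------------------- vectorize


def test_vectorize_round_trip_and_order():
    gray = np.ones((3, 3, 3), bool)
    rng = np.random.default_rng(1)
    maps = [rng.normal(size=(3, 3, 3)) for _ in range(4)]
    examples = [_example(m, label=1 if i % 2 == 0 else -1, sid=f"s{i}") for i, m in enumerate(maps)]
    mask = build_feature_mask(gray, [], threshold_percent=3.0)
    X, y, sids = vectorize_examples(examples, mask)
    assert X.shape == (4, 27)
    assert list(y) == [1, -1, 1, -1]
    assert list(sids) == ["s0", "s1", "s2", "s3"]
    back = mask.unmask(X[2])
    assert np.allclose(back, maps[2])


def test_vectorize_rejects_nan_inside_mask():
    gray = np.ones((3, 3, 3), bool)
    bad = np.zeros((3, 3, 3))
    bad[0, 0, 0] = np.nan
    mask = FeatureMask(include=gray)
    with pytest.raises(ExtractionError, match="non-finite"):
        vectorize_examples([_example(bad)], mask)


def test_feature_mask_serialization_round_trip(tmp_path):
    include = np.zeros((5, 5, 5), bool)
    include[1:4, 1:4, 1:4] = True
    mask = FeatureMask(include=include, affine=mni_like_affine((5, 5, 5), 4.0))
    mask.save(tmp_path / "mask")
    back = FeatureMask.load(tmp_path / "mask")
    assert np.array_equal(back.include, mask.include)
    assert np.array_equal(back.feature_order, mask.feature_order)


# ----------------------------------------------- synthetic round trip (noiseless)


def test_noiseless_round_trip_recovers_planted_amplitude(design):
    atlas = make_atlas(grid_shape=(10, 10, 10), seed=0, n_artifact_voxels=0)
    subject = simulate_subject(design, atlas, noise_sd=0.0, drift_amplitude=0.0, seed=0)
    examples = extract_subject_examples(subject)
    pain_vox = atlas.effect_pain == 0.5
    for e in examples:
        expected = 0.5 if e.label == 1 else atlas.effect_nonpain[pain_vox].max()
        assert np.allclose(e.psc[pain_vox], expected, atol=1e-10)


def test_artifact_voxels_survive_round_trip_and_get_filtered(design):
    atlas = make_atlas(grid_shape=(10, 10, 10), seed=0, n_artifact_voxels=2)
    subject = simulate_subject(design, atlas, noise_sd=0.0, drift_amplitude=0.0, seed=0)
    examples = extract_subject_examples(subject)
    art = atlas.artifact_mask
    for e in examples:
        assert (np.abs(e.psc[art]) > 3.0).all()
    mask = build_feature_mask(atlas.gray_mask, examples)
    assert not mask.include[art].any()
    assert mask.n_features == atlas.n_gray - 2
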