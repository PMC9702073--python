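"""TBR binning of FET segments and the relative-FD-vs-TBR fits."""

import numpy as np
import pytest

from lesionfd import (
    BinaryMask,
    CohortTruth,
    DensityImage,
    LesionSpec,
    ReferenceMap,
    TBRMap,
    bin_tbr_segments,
    fit_fd_tbr,
    generate_patient,
    generate_tbr_bin_cohort,
    make_ridges,
)
from lesionfd.synthetic import Ridge
from lesionfd.tbr import TBRBinResult, bins_to_frame


def _ball(grid, center, r):
    idx = np.indices(grid.shape).transpose(1, 2, 3, 0)
    return (((idx - np.asarray(center)) ** 2).sum(axis=-1)) <= r**2


def _ref(grid, value=10.0):
    return ReferenceMap(mean_fd=DensityImage(grid=grid, values=np.full(grid.shape, value)),
                        n_controls=2)


def test_uniform_hot_blob_yields_single_bin(grid16):
    blob = _ball(grid16, (8, 8, 8), 4)  # 257 voxels > 0.25 mL
    tbr = TBRMap(grid=grid16, values=np.where(blob, 2.0, 1.0))
    pat = DensityImage(grid=grid16, values=np.full(grid16.shape, 5.0))
    results = bin_tbr_segments(tbr, pat, _ref(grid16), subject="S1")
    included = [r for r in results if r.included]
    assert len(included) == 1
    (r,) = included
    assert r.bin_edges == (1.6, 2.6)
    assert r.mean_tbr == pytest.approx(2.0)
    assert r.relative_fd == pytest.approx(0.5)


def test_tiny_bin_excluded_for_min_volume(grid16):
    blob = _ball(grid16, (8, 8, 8), 3.2)  # ~137 voxels: 0.137 mL < 0.25 mL
    tbr = TBRMap(grid=grid16, values=np.where(blob, 2.0, 1.0))
    pat = DensityImage(grid=grid16, values=np.full(grid16.shape, 5.0))
    results = bin_tbr_segments(tbr, pat, _ref(grid16))
    assert len(results) == 1
    assert not results[0].included
    assert results[0].reason == "min_volume"


def test_bins_partition_the_fet_segment(grid16):
    rng = np.random.default_rng(4)
    vals = np.ones(grid16.shape)
    blob = _ball(grid16, (8, 8, 8), 5)
    vals[blob] = rng.uniform(1.61, 6.0, size=int(blob.sum()))
    tbr = TBRMap(grid=grid16, values=vals)
    pat = DensityImage(grid=grid16, values=np.full(grid16.shape, 5.0))
    results = bin_tbr_segments(tbr, pat, _ref(grid16))
    counts = [int(round(r.bin_volume_mL * 1000)) for r in results]
    assert sum(counts) == int(blob.sum())  # union of bins == segment, disjoint


def test_inhomogeneous_reference_excludes_subject(grid16):
    blob = _ball(grid16, (8, 8, 8), 4)
    tbr = TBRMap(grid=grid16, values=np.where(blob, 2.0, 1.0))
    # skewed field (rare hot planes): spatial SD exceeds the mean
    ref_vals = np.where(np.indices(grid16.shape)[0] % 4 == 0, 400.0, 0.5)
    ref = ReferenceMap(mean_fd=DensityImage(grid=grid16, values=ref_vals), n_controls=2)
    pat = DensityImage(grid=grid16, values=np.full(grid16.shape, 5.0))
    results = bin_tbr_segments(tbr, pat, ref)
    assert results and all(r.reason == "inhomogeneous_reference" for r in results)


def test_fiber_displacement_excludes_subject(grid16):
    blob = _ball(grid16, (8, 8, 8), 4)
    tbr = TBRMap(grid=grid16, values=np.where(blob, 2.0, 1.0))
    pat = DensityImage(grid=grid16, values=np.full(grid16.shape, 15.0))  # 150% of reference
    results = bin_tbr_segments(tbr, pat, _ref(grid16))
    assert results and all(r.reason == "exceeds_reference" for r in results)


def test_radial_gradient_bin_means_match_voxel_oracle(grid16):
    idx = np.indices(grid16.shape).transpose(1, 2, 3, 0)
    r = np.sqrt((((idx - 8.0) ** 2).sum(axis=-1)))
    vals = np.where(r <= 6.0, 5.5 - 0.5 * r, 1.0)  # radial TBR decay, >1.6 inside
    tbr = TBRMap(grid=grid16, values=np.maximum(vals, 1.0))
    pat = DensityImage(grid=grid16, values=np.full(grid16.shape, 5.0))
    results = bin_tbr_segments(tbr, pat, _ref(grid16))
    fet = tbr.values > 1.6
    for res in results:
        lo, hi = res.bin_edges
        sel = fet & (tbr.values > lo) & (tbr.values <= hi)
        assert res.mean_tbr == pytest.approx(tbr.values[sel].mean())
        assert res.bin_volume_mL == pytest.approx(sel.sum() / 1000.0)


def _bin(subject, tbr, fd, included=True):
    return TBRBinResult(subject=subject, bin_edges=(1.6, 2.6), mean_tbr=tbr,
                        relative_fd=fd, bin_volume_mL=1.0, included=included,
                        reason="" if included else "min_volume")


class TestFitFdTbr:
    def test_exact_line_recovered(self):
        bins = [_bin("S1", t, 0.6 - 0.08 * t) for t in (2.0, 3.0, 4.0, 5.0)]
        fit = fit_fd_tbr(bins, "simple_linear")
        assert fit.slope == pytest.approx(-0.08)
        assert fit.intercept == pytest.approx(0.6)
        assert fit.r_squared == pytest.approx(1.0)

    def test_constant_response_gives_zero_slope(self):
        bins = [_bin("S1", t, 0.5) for t in (2.0, 3.0, 4.0)]
        assert fit_fd_tbr(bins, "simple_linear").slope == pytest.approx(0.0, abs=1e-12)

    def test_excluded_bins_never_enter_the_fit(self):
        bins = [_bin("S1", t, 0.6 - 0.08 * t) for t in (2.0, 3.0)]
        bins += [_bin("S1", 5.0, 99.0, included=False)]
        fit = fit_fd_tbr(bins, "simple_linear")
        assert fit.n_obs == 2
        assert fit.slope == pytest.approx(-0.08)

    def test_mixed_model_needs_two_subjects(self):
        bins = [_bin("S1", t, 0.6 - 0.08 * t) for t in (2.0, 3.0, 4.0)]
        with pytest.raises(ValueError, match="2 subjects"):
            fit_fd_tbr(bins, "mixed_random_intercept")

    def test_too_few_bins_or_degenerate_tbr_rejected(self):
        with pytest.raises(ValueError, match="2 included bins"):
            fit_fd_tbr([_bin("S1", 2.0, 0.4)], "simple_linear")
        with pytest.raises(ValueError, match="distinct"):
            fit_fd_tbr([_bin("S1", 2.0, 0.4), _bin("S2", 2.0, 0.5)], "simple_linear")

    def test_mixed_model_recovers_slope_on_generated_bins(self):
        truth = CohortTruth(seed=19, tbr_slope=-0.08, tbr_intercept=0.6, tbr_intercept_sd=0.05)
        df = generate_tbr_bin_cohort(40, truth)
        df["included"] = True
        fit = fit_fd_tbr(df, "mixed_random_intercept")
        assert fit.slope_ci[0] <= -0.08 <= fit.slope_ci[1]
        assert 0.0 < fit.random_intercept_sd < 0.15

    def test_unknown_model_kind_rejected(self):
        with pytest.raises(ValueError, match="model kind"):
            fit_fd_tbr([_bin("S1", 2.0, 0.4), _bin("S1", 3.0, 0.3)], "cubic")


def test_zero_noise_linear_generator_recovers_slope_to_numerical_precision():
    """With a flat reference field and TBR-coupled suppression, pooled OLS on
    the image-derived bins returns the generator's slope and intercept."""
    from lesionfd import GridSpec, mean_density_map

    grid = GridSpec(shape=(24, 24, 24))
    truth = CohortTruth(seed=8, noise_sd=0.0, fet_tbr_coupling=True,
                        tbr_slope=-0.08, tbr_intercept=0.6)
    flat = [Ridge((12.0, 12.0, 12.0), (1.0, 0.0, 0.0), 50.0, 1e8)]
    layout = {"fet": LesionSpec((12.0, 12.0, 12.0), (8.0, 8.0, 8.0))}
    img, masks, _ = generate_patient(grid, truth, layout, ridges=flat)
    base = DensityImage(grid=grid, values=np.full(grid.shape, 50.0))
    ref = mean_density_map([base, base])
    results = bin_tbr_segments(masks.tbr, img, ref, subject="S1")
    fit = fit_fd_tbr([r for r in results if r.included], "simple_linear")
    assert fit.slope == pytest.approx(-0.08, abs=1e-6)
    assert fit.intercept == pytest.approx(0.6, abs=1e-5)


def test_bins_to_frame_roundtrip_columns():
    df = bins_to_frame([_bin("S1", 2.0, 0.4)])
    assert list(df["subject"]) == ["S1"]
    assert df.loc[0, "included"]
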