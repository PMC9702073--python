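"""Ground-truth properties of the synthetic cohort generator."""

import numpy as np
import pytest

from lesionfd import (
    CohortTruth,
    LesionSpec,
    SubjectRecord,
    default_lesion_layout,
    generate_control_cohort,
    generate_ecog,
    generate_patient,
    generate_streamlines,
    generate_tbr_bin_cohort,
    make_ridges,
    tract_field,
)


def test_zero_noise_controls_equal_the_analytic_field(grid16, zero_noise_truth):
    ridges = make_ridges(grid16, zero_noise_truth.seed)
    base = tract_field(grid16, ridges)
    cohort = generate_control_cohort(2, grid16, zero_noise_truth, ridges=ridges)
    for img, _ in cohort:
        np.testing.assert_array_equal(img.values, base)


def test_same_seed_gives_bit_identical_cohorts(grid16):
    truth = CohortTruth(seed=5, noise_sd=0.15)
    a = generate_control_cohort(3, grid16, truth)
    b = generate_control_cohort(3, grid16, truth)
    for (ia, ra), (ib, rb) in zip(a, b):
        np.testing.assert_array_equal(ia.values, ib.values)
        assert ra == rb


def test_cohort_mean_converges_to_the_noiseless_field(grid16):
    truth = CohortTruth(seed=9, noise_sd=0.1)
    ridges = make_ridges(grid16, truth.seed)
    base = tract_field(grid16, ridges)
    imgs = np.stack([im.values for im, _ in
                     generate_control_cohort(30, grid16, truth, ridges=ridges)])
    se = base * np.sqrt(np.exp(truth.noise_sd**2) - 1.0) / np.sqrt(30)
    frac_within = np.mean(np.abs(imgs.mean(axis=0) - base) <= 3 * se + 1e-12)
    assert frac_within >= 0.99


def test_unsuppressed_zero_noise_patient_equals_control_field(grid16):
    truth = CohortTruth(
        seed=2, noise_sd=0.0,
        suppression_ratio={"cavity": 1.0, "ce": 1.0, "fet": 1.0, "flair": 1.0},
    )
    ridges = make_ridges(grid16, truth.seed)
    img, _, _ = generate_patient(grid16, truth, default_lesion_layout(grid16), ridges=ridges)
    np.testing.assert_array_equal(img.values, tract_field(grid16, ridges))


def test_cavity_suppression_zero_empties_cavity_voxels(grid16):
    truth = CohortTruth(seed=2, noise_sd=0.0,
                        suppression_ratio={**dict.fromkeys(("ce", "fet", "flair"), 1.0), "cavity": 0.0})
    img, masks, _ = generate_patient(grid16, truth, default_lesion_layout(grid16))
    assert np.all(img.values[masks.masks["cavity"].values] == 0.0)


def test_half_suppression_gives_exact_masked_ratio(grid16):
    truth = CohortTruth(seed=4, noise_sd=0.0,
                        suppression_ratio=dict.fromkeys(("cavity", "ce", "fet", "flair"), 0.5))
    ridges = make_ridges(grid16, truth.seed)
    base = tract_field(grid16, ridges)
    img, masks, _ = generate_patient(grid16, truth, default_lesion_layout(grid16), ridges=ridges)
    for lt, m in masks.masks.items():
        ratio = img.values[m.values].mean() / base[m.values].mean()
        assert ratio == pytest.approx(0.5, abs=1e-12), lt


def test_recorded_volumes_equal_mask_voxel_count_times_voxel_volume(grid16):
    truth = CohortTruth(seed=6)
    img, masks, rec = generate_patient(grid16, truth, default_lesion_layout(grid16))
    for lt, m in masks.masks.items():
        assert rec.lesion_volumes_mL[lt] == m.n_voxels * grid16.voxel_volume_mm3 / 1000.0


@pytest.mark.parametrize("seed", [1, 2, 3])
def test_generated_fields_are_nonnegative(grid16, seed):
    truth = CohortTruth(seed=seed, noise_sd=0.3, fet_tbr_coupling=True)
    img, masks, _ = generate_patient(grid16, truth, default_lesion_layout(grid16))
    assert np.all(img.values >= 0)
    assert np.all(masks.tbr.values >= 0)


def test_cavity_overlapping_other_lesion_is_rejected(grid16):
    layout = {
        "cavity": LesionSpec((8.0, 8.0, 8.0), (3.0, 3.0, 3.0)),
        "ce": LesionSpec((9.0, 8.0, 8.0), (3.0, 3.0, 3.0)),
    }
    with pytest.raises(ValueError, match="cavity"):
        generate_patient(grid16, CohortTruth(seed=1), layout)


def test_invalid_suppression_ratio_rejected():
    with pytest.raises(ValueError, match="suppression"):
        CohortTruth(suppression_ratio={"ce": 1.3})
    with pytest.raises(ValueError, match="noise_sd"):
        CohortTruth(noise_sd=-0.1)


class TestEcogGeneration:
    @staticmethod
    def _records(n, fiber_loss):
        return [
            SubjectRecord(id=f"P{i:04d}", group="patient", age=50.0, gender="m",
                          education=2, fiber_loss=dict(fiber_loss))
            for i in range(n)
        ]

    def test_null_betas_give_half_impaired(self):
        truth = CohortTruth(seed=21, ecog_alpha=0.0,
                            ecog_betas=dict.fromkeys(("cavity", "ce", "fet", "flair"), 0.0))
        recs = generate_ecog(self._records(500, {"ce": 1000.0}), truth)
        frac = np.mean([r.ecog >= 1 for r in recs])
        assert abs(frac - 0.5) <= 3 * np.sqrt(0.25 / 500)

    def test_extreme_negative_intercept_gives_all_normal(self):
        truth = CohortTruth(seed=1, ecog_alpha=-50.0)
        recs = generate_ecog(self._records(100, {"ce": 100.0}), truth)
        assert all(r.ecog == 0 for r in recs)

    def test_impairment_monotone_in_fiber_loss_quartiles(self):
        truth = CohortTruth(seed=33, ecog_alpha=-2.0,
                            ecog_betas={"cavity": 0.0, "ce": 0.004, "fet": 0.0, "flair": 0.0})
        rng = np.random.default_rng(0)
        losses = rng.uniform(0, 2000, size=2000)
        recs = [SubjectRecord(id=f"P{i:04d}", group="patient", age=50.0, gender="f",
                              education=2, fiber_loss={"ce": float(fl)})
                for i, fl in enumerate(losses)]
        recs = generate_ecog(recs, truth)
        impaired = np.array([r.ecog >= 1 for r in recs])
        qs = np.quantile(losses, [0.25, 0.5, 0.75])
        rates = [impaired[losses <= qs[0]].mean(),
                 impaired[(losses > qs[0]) & (losses <= qs[1])].mean(),
                 impaired[(losses > qs[1]) & (losses <= qs[2])].mean(),
                 impaired[losses > qs[2]].mean()]
        assert all(a < b for a, b in zip(rates, rates[1:]))

    def test_missing_fiber_loss_is_an_error(self):
        rec = SubjectRecord(id="P0", group="patient", age=50.0, gender="m", education=2)
        with pytest.raises(ValueError, match="fiber-loss"):
            generate_ecog([rec], CohortTruth(seed=1))


class TestStreamlineGeneration:
    def test_zero_count_gives_empty_set(self, grid16):
        assert generate_streamlines(0, grid16, seed=1).count == 0

    def test_confined_to_bounding_box_and_deterministic(self, grid16):
        a = generate_streamlines(50, grid16, seed=8)
        b = generate_streamlines(50, grid16, seed=8)
        lo, hi = grid16.extent_mm()
        for sa, sb in zip(a, b):
            np.testing.assert_array_equal(sa, sb)
            assert np.all(sa >= lo) and np.all(sa < hi)
            assert sa.shape[0] >= 2


def test_tbr_bin_cohort_structure_and_determinism():
    truth = CohortTruth(seed=13, tbr_slope=-0.08, tbr_intercept=0.6)
    a = generate_tbr_bin_cohort(10, truth)
    b = generate_tbr_bin_cohort(10, truth)
    assert a.equals(b)
    assert len(a) == 40
    assert set(a.columns) == {"subject", "mean_tbr", "relative_fd"}
    assert (a["relative_fd"] >= 0).all()
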