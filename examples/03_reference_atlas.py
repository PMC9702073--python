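"""Propensity-match controls to patients and build the reference FD map.

The reference map (voxelwise mean FD over matched controls) is the
denominator of every relative fiber-density measure. Standardized mean
differences before/after matching show the covariate balance gained.
"""

from lesionfd import (
    CohortTruth, GridSpec, MatchSpec, generate_control_cohort,
    generate_patient_cohort, make_ridges, match_controls, mean_density_map,
    standardized_mean_differences,
)

grid = GridSpec(shape=(32, 32, 32))
truth = CohortTruth(seed=2, noise_sd=0.1)
ridges = make_ridges(grid, truth.seed)
patients = [rec for _, _, rec in generate_patient_cohort(15, grid, truth, ridges=ridges)]
pool = generate_control_cohort(40, grid, truth, ridges=ridges)
pool_recs = [rec for _, rec in pool]

match = match_controls(patients, pool_recs, MatchSpec())
by_id = {r.id: r for r in pool_recs}
matched = [by_id[c] for c in match.pairs["control_id"]]

print(match.pairs.head().to_string(index=False))
print("SMD before:", standardized_mean_differences(patients, pool_recs).round(3).to_dict())
print("SMD after: ", standardized_mean_differences(patients, matched).round(3).to_dict())

ref = mean_density_map([img for img, rec in pool if rec.id in set(match.pairs["control_id"])])
print(f"reference map over {ref.n_controls} matched controls, "
      f"mean FD {ref.mean_fd.values.mean():.1f} fibers/mm^3")
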