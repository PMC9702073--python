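"""Matched-control selection and the control-average fiber-density reference map.

The reference map is the voxelwise mean FD over matched healthy controls; it
is the denominator of every relative fiber-density measure. Controls are
selected by propensity-score matching: a main-effects logistic model of
patient membership on the matching covariates, then greedy nearest-neighbor
matching on the logit of the propensity, without replacement, patients
processed in descending propensity order (ties broken by subject id). An
optional caliper (max logit distance) leaves patients unmatched rather than
accept a poor match.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .grid import DensityImage
from .synthetic import SubjectRecord


@dataclass(frozen=True)
class MatchSpec:
    covariates: tuple[str, ...] = ("age", "gender", "education")
    caliper: float | None = None  # max |logit propensity| distance
    ratio: int = 1  # controls per patient

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError("at least one matching covariate is required")
        if self.caliper is not None and self.caliper < 0:
            raise ValueError("caliper must be nonnegative")
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")


@dataclass
class ReferenceMap:
    mean_fd: DensityImage
    n_controls: int

    def __post_init__(self) -> None:
        if self.n_controls < 2:
            raise ValueError("reference map requires at least 2 controls")


@dataclass
class MatchResult:
    pairs: pd.DataFrame  # patient_id, control_id, propensity_patient, propensity_control
    unmatched_patients: list = field(default_factory=list)
    dropped_covariates: list = field(default_factory=list)


def _records_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        rows.append({
            "id": r.id,
            "age": r.age,
            "gender": 1.0 if r.gender == "m" else 0.0,
            "education": float(r.education),
        })
    return pd.DataFrame(rows).set_index("id")


def match_controls(
    patients: list[SubjectRecord], pool: list[SubjectRecord], spec: MatchSpec = MatchSpec()
) -> MatchResult:
    """Greedy 1:ratio propensity-score matching of controls to patients.

    Covariates with a single level across the combined sample are dropped
    with a warning (matching proceeds on the remainder). Raises if the pool
    is smaller than ``len(patients) * ratio``.
    """
    if len(pool) < len(patients) * spec.ratio:
        raise ValueError("control pool too small for requested matching ratio")
    pf, cf = _records_frame(patients), _records_frame(pool)
    both = pd.concat([pf, cf])
    y = np.r_[np.ones(len(pf)), np.zeros(len(cf))]

    covs, dropped = [], []
    for c in spec.covariates:
        if c not in both.columns:
            raise KeyError(f"unknown matching covariate {c!r}")
        (dropped if both[c].nunique() < 2 else covs).append(c)
    if dropped:
        warnings.warn(f"dropping single-level covariates from matching: {dropped}")
    if not covs:
        raise ValueError("no usable matching covariates (all single-level)")

    X = sm.add_constant(both[covs].to_numpy(), has_constant="add")
    model = sm.Logit(y, X)
    try:
        fit = model.fit(disp=0, maxiter=200)
        if not np.all(np.isfinite(fit.params)):
            raise np.linalg.LinAlgError
    except Exception:
        # separation or singular Hessian on small samples: ridge-penalized fit
        fit = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
    eta = X @ fit.params  # logit of the propensity
    logit_p = pd.Series(eta, index=both.index)
    prop = pd.Series(1.0 / (1.0 + np.exp(-eta)), index=both.index)

    order = sorted(pf.index, key=lambda i: (-logit_p[i], i))
    available = sorted(cf.index)
    rows, unmatched = [], []
    for pid in order:
        got = 0
        for _ in range(spec.ratio):
            if not available:
                break
            best = min(available, key=lambda cid: (abs(logit_p[cid] - logit_p[pid]), cid))
            dist = abs(logit_p[best] - logit_p[pid])
            if spec.caliper is not None and dist > spec.caliper:
                break
            available.remove(best)
            rows.append({
                "patient_id": pid, "control_id": best,
                "propensity_patient": float(prop[pid]),
                "propensity_control": float(prop[best]),
            })
            got += 1
        if got < spec.ratio:
            unmatched.append(pid)
    pairs = pd.DataFrame(rows, columns=["patient_id", "control_id", "propensity_patient", "propensity_control"])
    return MatchResult(pairs=pairs, unmatched_patients=unmatched, dropped_covariates=dropped)


def standardized_mean_differences(
    patients: list[SubjectRecord], controls: list[SubjectRecord],
    covariates: tuple[str, ...] = ("age", "gender", "education"),
) -> pd.Series:
    """Absolute standardized mean difference per covariate (pooled SD)."""
    pf, cf = _records_frame(patients), _records_frame(controls)
    out = {}
    for c in covariates:
        mp, mc = pf[c].mean(), cf[c].mean()
        sp = np.sqrt((pf[c].var(ddof=1) + cf[c].var(ddof=1)) / 2.0)
        out[c] = 0.0 if sp == 0 else abs(mp - mc) / sp
    return pd.Series(out)


def mean_density_map(images: list[DensityImage]) -> ReferenceMap:
    """Voxelwise arithmetic mean FD over >= 2 images on one grid."""
    if len(images) < 2:
        raise ValueError("need at least 2 images for a reference map")
    grid = images[0].grid
    for im in images[1:]:
        if im.grid != grid:
            raise ValueError("all images must share one grid")
    mean = np.mean([im.values for im in images], axis=0)
    return ReferenceMap(mean_fd=DensityImage(grid=grid, values=mean), n_controls=len(images))
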