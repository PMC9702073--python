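"""TBR binning of FET lesions and the relative-FD-vs-uptake models.

Amino-acid-PET uptake (tumor-to-brain ratio, TBR) inside the FET lesion is
divided into four bins above the 1.6 glioma-tissue cutoff: (1.6, 2.6],
(2.6, 3.6], (3.6, 4.6] and (4.6, inf). Bins are half-open at the bottom,
matching the strictly-above-1.6 segmentation. Per included bin the mean TBR
and the relative fiber density are computed; bins smaller than 0.25 mL are
excluded as unreliable, and a subject is excluded altogether if the
reference FD under the FET segment is inhomogeneous (spatial SD >= mean) or
if displaced fibers push the full-segment relative FD above the reference
(relative FD > 1 by default).

Two models relate relative FD to TBR: pooled ordinary least squares over all
included bins, and a linear mixed model with TBR as fixed effect and a
subject-level random intercept (no random slope), fit by maximum likelihood
so nested-model comparisons remain valid.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf

from .atlas import ReferenceMap
from .grid import BinaryMask, DensityImage, TBRMap
from .lesions import homogeneity_ok, segment_from_tbr, segment_stats

DEFAULT_EDGES = (1.6, 2.6, 3.6, 4.6, np.inf)
MIN_BIN_VOLUME_ML = 0.25


@dataclass
class TBRBinResult:
    subject: str
    bin_edges: tuple[float, float]
    mean_tbr: float
    relative_fd: float
    bin_volume_mL: float
    included: bool
    reason: str = ""  # exclusion reason when not included


@dataclass
class TbrFdFit:
    slope: float
    intercept: float
    slope_se: float
    p_value: float
    r_squared: float  # NaN for the mixed model
    model_kind: str  # "simple_linear" | "mixed_random_intercept"
    n_obs: int
    slope_ci: tuple[float, float]
    random_intercept_sd: float = float("nan")


def bin_tbr_segments(
    tbr: TBRMap,
    patient_fd: DensityImage,
    reference: ReferenceMap,
    subject: str = "P0000",
    fet_mask: BinaryMask | None = None,
    edges: tuple[float, ...] = DEFAULT_EDGES,
    min_volume_mL: float = MIN_BIN_VOLUME_ML,
    exceedance_threshold: float = 1.0,
) -> list[TBRBinResult]:
    """Bin one subject's FET segment by TBR and attach relative FD per bin.

    Exclusions are reported, never raised: an inhomogeneous or
    fiber-displacement subject gets all bins flagged (reasons
    "inhomogeneous_reference" / "exceeds_reference"), undersized bins get
    "min_volume", and empty bins are simply absent. The bin voxel sets
    partition the cleaned FET segment.
    """
    if fet_mask is None:
        fet_mask = segment_from_tbr(tbr)
    if fet_mask.n_voxels == 0:
        return []
    full = segment_stats(patient_fd, reference, fet_mask)
    subject_reason = ""
    if not full.valid or not homogeneity_ok(full):
        subject_reason = "inhomogeneous_reference"
    elif full.relative_fd > exceedance_threshold:
        subject_reason = "exceeds_reference"

    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = fet_mask.values & (tbr.values > lo) & (tbr.values <= hi)
        n_vox = int(sel.sum())
        if n_vox == 0:
            continue
        vol_mL = n_vox * tbr.grid.voxel_volume_mm3 / 1000.0
        bin_mask = BinaryMask(grid=tbr.grid, values=sel, lesion_type="fet")
        stats = segment_stats(patient_fd, reference, bin_mask)
        mean_tbr = float(tbr.values[sel].mean())
        reason = subject_reason
        if not reason and vol_mL < min_volume_mL:
            reason = "min_volume"
        if not reason and not stats.valid:
            reason = "zero_reference"
        out.append(TBRBinResult(
            subject=subject,
            bin_edges=(float(lo), float(hi)),
            mean_tbr=mean_tbr,
            relative_fd=stats.relative_fd if stats.valid else float("nan"),
            bin_volume_mL=vol_mL,
            included=not reason,
            reason=reason,
        ))
    return out


def bins_to_frame(results: list[TBRBinResult]) -> pd.DataFrame:
    rows = [{
        "subject": r.subject, "bin_low": r.bin_edges[0], "bin_high": r.bin_edges[1],
        "mean_tbr": r.mean_tbr, "relative_fd": r.relative_fd,
        "bin_volume_mL": r.bin_volume_mL, "included": r.included, "reason": r.reason,
    } for r in results]
    return pd.DataFrame(rows, columns=[
        "subject", "bin_low", "bin_high", "mean_tbr", "relative_fd",
        "bin_volume_mL", "included", "reason",
    ])


def _included_frame(results) -> pd.DataFrame:
    if isinstance(results, pd.DataFrame):
        df = results.copy()
        if "included" in df.columns:
            df = df[df["included"]]
    else:
        df = bins_to_frame(results)
        df = df[df["included"]]
    df = df.dropna(subset=["mean_tbr", "relative_fd"])
    return df


def fit_fd_tbr(results, model_kind: str = "simple_linear") -> TbrFdFit:
    """Fit relative FD on mean TBR over included bins.

    ``simple_linear`` pools bins in one OLS; ``mixed_random_intercept`` adds
    a subject-level random intercept, fit by maximum likelihood. Excluded
    bins never enter the fit.
    """
    df = _included_frame(results)
    if len(df) < 2:
        raise ValueError("need at least 2 included bins to fit")
    if df["mean_tbr"].nunique() < 2:
        raise ValueError("need at least 2 distinct mean TBR values")

    if model_kind == "simple_linear":
        X = sm.add_constant(df["mean_tbr"].to_numpy())
        fit = sm.OLS(df["relative_fd"].to_numpy(), X).fit()
        ci = fit.conf_int()[1]
        return TbrFdFit(
            slope=float(fit.params[1]), intercept=float(fit.params[0]),
            slope_se=float(fit.bse[1]), p_value=float(fit.pvalues[1]),
            r_squared=float(fit.rsquared), model_kind=model_kind,
            n_obs=len(df), slope_ci=(float(ci[0]), float(ci[1])),
        )
    if model_kind == "mixed_random_intercept":
        if df["subject"].nunique() < 2:
            raise ValueError("mixed model requires bins from at least 2 subjects")
        model = smf.mixedlm("relative_fd ~ mean_tbr", df, groups=df["subject"])
        import warnings
        from statsmodels.tools.sm_exceptions import ConvergenceWarning
        with warnings.catch_warnings():
            # a near-zero random-intercept variance legitimately sits on the
            # parameter boundary; the fixed-effect estimates are unaffected
            warnings.simplefilter("ignore", ConvergenceWarning)
            fit = model.fit(reml=False)
        se = float(fit.bse["mean_tbr"])
        slope = float(fit.params["mean_tbr"])
        ci = (slope - 1.959963984540054 * se, slope + 1.959963984540054 * se)
        return TbrFdFit(
            slope=slope, intercept=float(fit.params["Intercept"]),
            slope_se=se, p_value=float(fit.pvalues["mean_tbr"]),
            r_squared=float("nan"), model_kind=model_kind,
            n_obs=len(df), slope_ci=ci,
            random_intercept_sd=float(np.sqrt(max(fit.cov_re.iloc[0, 0], 0.0))),
        )
    raise ValueError(f"unknown model kind {model_kind!r}")
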