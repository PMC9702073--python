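"""Cohort-level statistics: lesion-type summaries, group tests and ECOG models.

The battery mirrors a standard nonparametric neuro-oncology analysis:

* per lesion type, absolute FD in patients versus the control reference by
  two-sided Mann-Whitney U, and relative FD against 100% of reference by a
  two-sided one-sample Wilcoxon signed-rank test (Pratt handling of zero
  differences, for determinism);
* across lesion types, a Kruskal-Wallis omnibus test with pairwise
  Mann-Whitney post-hoc comparisons (uncorrected by default; Bonferroni or
  Holm available);
* performance status (ECOG 0 = normal vs >= 1 = impaired) modeled by
  univariate and multivariate maximum-likelihood logistic regression on the
  per-lesion-type total fiber loss, with clinical covariates available as
  confounders. Perfect separation is detected, flagged and handled by an
  L2-penalized refit (labeled; no p-values are reported for it).

An outlier rule is applied before summarizing (default: drop segments with
relative FD > 1.5, i.e. implausibly above reference); every exclusion is
logged in the returned objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .grid import LESION_TYPES
from .synthetic import SubjectRecord

DEFAULT_OUTLIER_RELATIVE_FD = 1.5
UNDERPOWERED_N = 5


@dataclass
class LesionTypeSummary:
    lesion_type: str
    n_subjects: int
    volume_mean_mL: float
    volume_sd_mL: float
    volume_median_mL: float
    fd_healthy_mean: float
    fd_healthy_sd: float
    fd_patient_mean: float
    fd_patient_sd: float
    relative_fd_mean_pct: float
    relative_fd_sd_pct: float
    p_absolute: float
    p_relative: float
    underpowered: bool
    n_excluded_outliers: int


@dataclass
class EcogModelResult:
    predictor: str
    coefficient: float
    p_value: float
    model: str  # "univariate" | "multivariate"
    odds_ratio: float = float("nan")
    flagged_separation: bool = False


@dataclass
class AcrossTypeComparison:
    omnibus_p: float
    pairwise_p: dict = field(default_factory=dict)  # (type_a, type_b) -> p
    correction: str = "none"


def _mannwhitney_p(x, y) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    if np.all(x == y[0] if len(set(y)) == 1 else False) and len(set(x)) == 1 and x[0] == y[0]:
        return 1.0
    pooled = np.concatenate([x, y])
    if np.ptp(pooled) == 0:
        return 1.0  # every observation tied: no evidence of a shift
    return float(sps.mannwhitneyu(x, y, alternative="two-sided").pvalue)


def _wilcoxon_one_sample_p(diffs) -> float:
    d = np.asarray(diffs, float)
    if np.all(d == 0):
        return 1.0  # all differences zero: Pratt ranking leaves nothing to test
    return float(sps.wilcoxon(d, zero_method="pratt", alternative="two-sided").pvalue)


def segment_frame(rows: list[tuple[str, object]]) -> pd.DataFrame:
    """Long-format frame from (subject_id, SegmentStats) pairs."""
    recs = []
    for sid, s in rows:
        recs.append({
            "subject": sid, "lesion_type": s.lesion_type, "volume_mL": s.volume_mL,
            "patient_mean_fd": s.patient_mean_fd, "reference_mean_fd": s.reference_mean_fd,
            "relative_fd": s.relative_fd if s.valid else np.nan,
        })
    return pd.DataFrame(recs, columns=[
        "subject", "lesion_type", "volume_mL", "patient_mean_fd",
        "reference_mean_fd", "relative_fd",
    ])


def summarize_lesion_types(
    segments: pd.DataFrame, outlier_relative_fd: float | None = DEFAULT_OUTLIER_RELATIVE_FD
) -> list[LesionTypeSummary]:
    """Per-lesion-type volume/FD summary with the two primary tests.

    ``segments`` is the long frame from :func:`segment_frame`. Lesion types
    with no subjects are omitted with a warning. Small groups are flagged
    underpowered rather than suppressed.
    """
    out = []
    for lt in LESION_TYPES:
        df = segments[segments["lesion_type"] == lt].dropna(subset=["relative_fd"])
        if df.empty:
            warnings.warn(f"no subjects with lesion type {lt!r}; omitted from summary")
            continue
        n_out = 0
        if outlier_relative_fd is not None:
            keep = df["relative_fd"] <= outlier_relative_fd
            n_out = int((~keep).sum())
            df = df[keep]
            if df.empty:
                warnings.warn(f"all {lt!r} segments excluded by outlier rule")
                continue
        rel = df["relative_fd"].to_numpy()
        out.append(LesionTypeSummary(
            lesion_type=lt,
            n_subjects=len(df),
            volume_mean_mL=float(df["volume_mL"].mean()),
            volume_sd_mL=float(df["volume_mL"].std(ddof=1)) if len(df) > 1 else 0.0,
            volume_median_mL=float(df["volume_mL"].median()),
            fd_healthy_mean=float(df["reference_mean_fd"].mean()),
            fd_healthy_sd=float(df["reference_mean_fd"].std(ddof=1)) if len(df) > 1 else 0.0,
            fd_patient_mean=float(df["patient_mean_fd"].mean()),
            fd_patient_sd=float(df["patient_mean_fd"].std(ddof=1)) if len(df) > 1 else 0.0,
            relative_fd_mean_pct=float(rel.mean() * 100.0),
            relative_fd_sd_pct=float(rel.std(ddof=1) * 100.0) if len(df) > 1 else 0.0,
            p_absolute=_mannwhitney_p(df["patient_mean_fd"], df["reference_mean_fd"]),
            p_relative=_wilcoxon_one_sample_p(rel - 1.0),
            underpowered=len(df) < UNDERPOWERED_N,
            n_excluded_outliers=n_out,
        ))
    return out


def compare_across_types(
    relative_fd_by_type: dict[str, np.ndarray], correction: str = "none"
) -> AcrossTypeComparison:
    """Kruskal-Wallis omnibus plus pairwise Mann-Whitney post-hoc tests."""
    groups = {k: np.asarray(v, float) for k, v in relative_fd_by_type.items() if len(v) >= 2}
    if len(groups) < 2:
        raise ValueError("need at least 2 lesion types with >= 2 subjects each")
    arrays = list(groups.values())
    pooled = np.concatenate(arrays)
    if np.ptp(pooled) == 0:
        omnibus = 1.0
    else:
        omnibus = float(sps.kruskal(*arrays).pvalue)
    names = sorted(groups)
    pairs, pvals = [], []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            pairs.append((a, b))
            pvals.append(_mannwhitney_p(groups[a], groups[b]))
    if correction != "none" and pvals:
        pvals = list(multipletests(pvals, method=correction)[1])
    return AcrossTypeComparison(
        omnibus_p=omnibus, pairwise_p=dict(zip(pairs, pvals)), correction=correction
    )


CLINICAL_COVARIATES = (
    "age", "gender", "resection_type", "grade", "n_surgeries",
    "n_radiotherapy", "n_chemotherapy", "months_since_rt",
)


def fiberloss_frame(records: list[SubjectRecord]) -> pd.DataFrame:
    """Wide analysis frame: one row per subject, fiber loss per lesion type."""
    rows = []
    for r in records:
        if r.fiber_loss is None:
            raise ValueError(f"subject {r.id} has no fiber-loss values")
        row = {
            "subject": r.id, "impaired": int(r.ecog >= 1), "age": r.age,
            "gender": 1.0 if r.gender == "m" else 0.0,
            "months_since_rt": r.months_since_rt if r.months_since_rt is not None else 0.0,
        }
        for lt in LESION_TYPES:
            row[f"fl_{lt}"] = float(r.fiber_loss.get(lt, 0.0))
        rows.append(row)
    return pd.DataFrame(rows)


def _fit_logit(y: np.ndarray, X: np.ndarray):
    """Maximum-likelihood logit; on separation return (fit, True) via L2 refit."""
    model = sm.Logit(y, X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        try:
            fit = model.fit(disp=0, maxiter=200)
            if np.all(np.isfinite(fit.bse)):
                return fit, False
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            pass
    fit = model.fit_regularized(alpha=1.0, L1_wt=0.0, disp=0)
    return fit, True


def ecog_regression(
    data: pd.DataFrame,
    mode: str = "univariate",
    predictors: tuple[str, ...] | None = None,
    covariates: tuple[str, ...] = (),
) -> list[EcogModelResult]:
    """Logistic regression of impaired ECOG on total fiber loss.

    ``data`` is the frame from :func:`fiberloss_frame` (column ``impaired``
    is the outcome). Univariate mode fits each predictor alone; multivariate
    mode fits all fiber-loss predictors jointly, plus any requested clinical
    covariates. Raises on a single-class outcome.
    """
    if predictors is None:
        predictors = tuple(f"fl_{lt}" for lt in LESION_TYPES)
    y = data["impaired"].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("single-class outcome: ECOG dichotomy has no variation")

    results: list[EcogModelResult] = []
    if mode == "univariate":
        for pred in predictors:
            X = sm.add_constant(data[[pred]].to_numpy(), has_constant="add")
            fit, flagged = _fit_logit(y, X)
            coef = float(fit.params[1])
            results.append(EcogModelResult(
                predictor=pred, coefficient=coef,
                p_value=float(fit.pvalues[1]) if not flagged else float("nan"),
                model="univariate", odds_ratio=float(np.exp(coef)),
                flagged_separation=flagged,
            ))
    elif mode == "multivariate":
        cols = list(predictors) + [c for c in covariates if c in data.columns]
        X = sm.add_constant(data[cols].to_numpy(), has_constant="add")
        fit, flagged = _fit_logit(y, X)
        for j, pred in enumerate(cols, start=1):
            coef = float(fit.params[j])
            results.append(EcogModelResult(
                predictor=pred, coefficient=coef,
                p_value=float(fit.pvalues[j]) if not flagged else float("nan"),
                model="multivariate", odds_ratio=float(np.exp(coef)),
                flagged_separation=flagged,
            ))
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return results
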