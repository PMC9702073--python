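"""T2/FLAIR lesion classification and the total-fiber-loss statistic.

T2/FLAIR hyperintensities after multimodal glioma therapy can reflect either
peritumoral edema around recurrent tumor or radiation-induced gliosis. The
prevailing characteristics assign one label per subject:

* edema — recurrent tumor larger than 10 mL in *both* the
  contrast-enhancing and the FET-uptake images;
* gliosis — near-complete absence of contrast enhancement and FET uptake
  (each below 0.1 mL) and more than 6 months since radiotherapy;
* unclassified otherwise.

Total fiber loss converts a segment's relative FD deficit into an absolute
amount of lost fiber: (1 - relative FD) x segment volume (mm^3). An absent
lesion contributes zero. Segments whose FD exceeds the reference (displaced
fibers) would yield negative loss; these are floored at zero by default.
"""

from __future__ import annotations

from dataclasses import dataclass

from .lesions import SegmentStats

EDEMA_MIN_VOLUME_ML = 10.0
GLIOSIS_MAX_VOLUME_ML = 0.1
GLIOSIS_MIN_MONTHS = 6.0


@dataclass(frozen=True)
class FlairClass:
    label: str  # "edema" | "gliosis" | "unclassified"
    ce_volume_mL: float
    fet_volume_mL: float
    months_since_rt: float | None


@dataclass(frozen=True)
class FiberLossRecord:
    subject: str
    lesion_type: str
    total_fiber_loss: float  # (1 - relative FD) x volume, mm^3
    relative_reduction: float  # 1 - relative FD (possibly floored)
    segment_volume_mm3: float


def classify_t2flair(
    ce_volume_mL: float, fet_volume_mL: float, months_since_rt: float | None
) -> FlairClass:
    """Assign edema/gliosis/unclassified from tumor burden and RT interval.

    All three thresholds are strict (>10 mL, <0.1 mL, >6 months); the two
    rules are mutually exclusive by construction, edema evaluated first.
    A missing RT interval can never satisfy the gliosis rule.
    """
    if ce_volume_mL < 0 or fet_volume_mL < 0:
        raise ValueError("lesion volumes must be nonnegative")
    if months_since_rt is not None and months_since_rt < 0:
        raise ValueError("months_since_rt must be nonnegative")
    if ce_volume_mL > EDEMA_MIN_VOLUME_ML and fet_volume_mL > EDEMA_MIN_VOLUME_ML:
        label = "edema"
    elif (
        ce_volume_mL < GLIOSIS_MAX_VOLUME_ML
        and fet_volume_mL < GLIOSIS_MAX_VOLUME_ML
        and months_since_rt is not None
        and months_since_rt > GLIOSIS_MIN_MONTHS
    ):
        label = "gliosis"
    else:
        label = "unclassified"
    return FlairClass(label, ce_volume_mL, fet_volume_mL, months_since_rt)


def total_fiber_loss(
    stats: SegmentStats | None,
    subject: str = "",
    lesion_type: str = "",
    allow_negative: bool = False,
) -> FiberLossRecord:
    """Total fiber loss of one segment; absent lesions contribute zero."""
    if stats is None:
        return FiberLossRecord(subject, lesion_type, 0.0, 0.0, 0.0)
    reduction = 1.0 - stats.relative_fd
    if not allow_negative:
        reduction = max(reduction, 0.0)
    return FiberLossRecord(
        subject=subject,
        lesion_type=lesion_type or stats.lesion_type,
        total_fiber_loss=reduction * stats.volume_mm3,
        relative_reduction=reduction,
        segment_volume_mm3=stats.volume_mm3,
    )
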