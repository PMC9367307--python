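"""Voxel-wise agreement metrics for an ordered (reference, comparison) pair.

The reference ("ground truth") mask defines the false negatives; the
comparison mask defines the false positives.  Four metrics are computed
from one confusion tally:

* ``DSC = 2TP / (2TP + FP + FN)`` — spatial overlap.
* ``AUC = 1 - 1/2 [ FP/(FP+TN) + FN/(FN+TP) ]`` — single-point ROC-area
  surrogate for a binary mask pair; depends on the background (TN) size.
* ``FPRm = FP / (TP + FN)`` — false positives normalised by the reference
  mask size rather than by the background, because TN voxels are image
  background and dwarf any mask.  Reported as ``1 - FPRm``.
* ``FNR = FN / (TP + FN) = 1 - sensitivity``.  Reported as ``1 - FNR``.

``1 - FPRm`` can go negative when the comparison mask hallucinates more
voxels than the whole reference; by default it is clamped at 0 and the
raw value kept alongside a flag.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mask_io import MaskVolume, MaskGeometryError, check_compatible

__all__ = [
    "ConfusionCounts",
    "AgreementMetrics",
    "confusion_counts",
    "dsc",
    "auc_pairwise",
    "one_minus_fprm",
    "one_minus_fnr",
    "evaluate_pair",
    "metrics_from_counts",
    "pair_record",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = ("dsc", "auc", "one_minus_fprm", "one_minus_fnr")


@dataclass(frozen=True)
class ConfusionCounts:
    """Voxel tallies for one ordered mask pair on a shared grid."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a nonnegative integer, got {v}")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @property
    def reference_size(self) -> int:
        """Foreground size of the reference mask (TP + FN)."""
        return self.tp + self.fn


@dataclass(frozen=True)
class AgreementMetrics:
    """The four per-case metrics plus clamping bookkeeping."""

    dsc: float
    auc: float
    one_minus_fprm: float
    one_minus_fnr: float
    fprm_clamped: bool
    one_minus_fprm_raw: float
    counts: ConfusionCounts


def confusion_counts(gt: MaskVolume, cmp: MaskVolume) -> ConfusionCounts:
    """Tally TP/FP/FN/TN between a reference and a comparison mask.

    Order matters: voxels only in ``gt`` are FN, voxels only in ``cmp``
    are FP.  TN is counted over the shared grid (the image background).
    """
    compat = check_compatible(gt, cmp)
    if not compat:
        raise MaskGeometryError(
            f"masks not comparable ({compat.reason}); "
            f"gt shape={gt.shape} spacing={gt.spacing}, "
            f"cmp shape={cmp.shape} spacing={cmp.spacing}"
        )
    a = gt.voxels.astype(bool)
    b = cmp.voxels.astype(bool)
    tp = int(np.count_nonzero(a & b))
    fp = int(np.count_nonzero(~a & b))
    fn = int(np.count_nonzero(a & ~b))
    tn = a.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP/(2TP+FP+FN).

    Undefined (raises) when both masks are empty; an empty comparison
    mask against a nonempty reference scores 0.
    """
    denom = 2 * c.tp + c.fp + c.fn
    if denom == 0:
        raise ValueError("DSC undefined: both masks are empty (0/0)")
    return 2.0 * c.tp / denom


def auc_pairwise(c: ConfusionCounts) -> float:
    """Two-mask ROC-area surrogate 1 - (FPR + FNR)/2 on the shared grid."""
    if c.tp + c.fn == 0:
        raise ValueError("AUC undefined: reference mask is empty")
    if c.fp + c.tn == 0:
        raise ValueError("AUC undefined: grid has no background voxels")
    fpr = c.fp / (c.fp + c.tn)
    fnr = c.fn / (c.fn + c.tp)
    return 1.0 - 0.5 * (fpr + fnr)


def one_minus_fprm(c: ConfusionCounts, clamp: bool = True) -> float:
    """1 - FP/(TP+FN): agreement in the false-positive direction.

    With ``clamp`` (default) values below 0 are floored at 0, matching
    the convention that 0 denotes null similitude.
    """
    ref = c.reference_size
    if ref == 0:
        raise ValueError("FPRm undefined: reference mask is empty")
    raw = 1.0 - c.fp / ref
    if clamp and raw < 0.0:
        return 0.0
    return raw


def one_minus_fnr(c: ConfusionCounts) -> float:
    """1 - FN/(TP+FN), identically TP/(TP+FN) (sensitivity/recall)."""
    ref = c.reference_size
    if ref == 0:
        raise ValueError("FNR undefined: reference mask is empty")
    # computed as tp/ref, not 1 - fn/ref: identical algebraically, but
    # exact in floating point so the sensitivity identity holds to the ulp
    return c.tp / ref


def metrics_from_counts(c: ConfusionCounts) -> AgreementMetrics:
    """All four metrics from one confusion tally (reference nonempty)."""
    raw = one_minus_fprm(c, clamp=False)
    clamped = raw < 0.0
    return AgreementMetrics(
        dsc=dsc(c),
        auc=auc_pairwise(c),
        one_minus_fprm=max(raw, 0.0),
        one_minus_fnr=one_minus_fnr(c),
        fprm_clamped=clamped,
        one_minus_fprm_raw=raw,
        counts=c,
    )


def evaluate_pair(gt: MaskVolume, cmp: MaskVolume) -> AgreementMetrics:
    """Compute all four agreement metrics for a compatible mask pair."""
    c = confusion_counts(gt, cmp)
    if c.reference_size == 0:
        raise ValueError("reference mask is empty; agreement metrics undefined")
    return metrics_from_counts(c)


def pair_record(gt: MaskVolume, cmp: MaskVolume, case_id: str | None = None) -> dict:
    """One flat per-case row (counts + metrics) for tabular output."""
    m = evaluate_pair(gt, cmp)
    c = m.counts
    return {
        "case_id": case_id if case_id is not None else gt.case_id,
        "tp": c.tp,
        "fp": c.fp,
        "fn": c.fn,
        "tn": c.tn,
        "dsc": m.dsc,
        "auc": m.auc,
        "one_minus_fprm": m.one_minus_fprm,
        "one_minus_fnr": m.one_minus_fnr,
        "fprm_clamped": m.fprm_clamped,
    }
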