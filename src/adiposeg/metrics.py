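"""Segmentation evaluation: Dice coefficient and pixel error with
per-slice, per-examination, and per-group aggregation.

Dice between a reference mask R and a predicted mask P is
``2·|R∩P| / (|R| + |P|)``.  Pixel error is the percentage of image
pixels on which the two masks disagree, ``100·|RΔP| / (W·H)`` with Δ
the symmetric difference.  Per-class metrics are computed slicewise on
the class-restricted binary masks and averaged across all slices of all
examinations, as mean ± SD per group and compartment.
"""

from __future__ import annotations

import numpy as np

from .core import SAT, VAT, CLASS_NAMES, LabelMap, SegMetrics

__all__ = ["dice", "pixel_error", "evaluate_examination", "aggregate_group",
           "volumetric_dice"]


def _check_same_shape(R, P):
    R = np.asarray(R, dtype=bool)
    P = np.asarray(P, dtype=bool)
    if R.shape != P.shape:
        raise ValueError(f"mask shape mismatch: {R.shape} vs {P.shape}")
    return R, P


def dice(R, P) -> float:
    """Dice overlap 2|R∩P|/(|R|+|P|); NaN flags the undefined
    empty-vs-empty case (handled at aggregation)."""
    R, P = _check_same_shape(R, P)
    denom = int(R.sum()) + int(P.sum())
    if denom == 0:
        return float("nan")
    return 2.0 * int((R & P).sum()) / denom


def pixel_error(R, P) -> float:
    """Percentage of pixels on which the masks disagree."""
    R, P = _check_same_shape(R, P)
    return 100.0 * int((R ^ P).sum()) / R.size


def volumetric_dice(ref: LabelMap, pred: LabelMap, cls: int) -> float:
    """Single whole-volume Dice for one class (secondary summary)."""
    return dice(ref.classes == cls, pred.classes == cls)


def evaluate_examination(ref: LabelMap, pred: LabelMap,
                         empty_policy: str = "exclude",
                         ) -> dict[str, dict[str, list[float]]]:
    """Per-slice Dice and pixel error for SAT and VAT.

    Parameters
    ----------
    empty_policy : "exclude" | "one"
        How to treat slices where both masks are empty for a class:
        drop them from that class's list (default) or score Dice 1.
    """
    if ref.shape != pred.shape:
        raise ValueError(f"grid mismatch: {ref.shape} vs {pred.shape}")
    if empty_policy not in ("exclude", "one"):
        raise ValueError(f"unknown empty_policy {empty_policy!r}")
    out: dict[str, dict[str, list[float]]] = {}
    for cls in (SAT, VAT):
        name = CLASS_NAMES[cls]
        dices, errors = [], []
        for z in range(ref.shape[2]):
            r = ref.classes[:, :, z] == cls
            p = pred.classes[:, :, z] == cls
            d = dice(r, p)
            if np.isnan(d):
                if empty_policy == "exclude":
                    continue
                d = 1.0
            dices.append(d)
            errors.append(pixel_error(r, p))
        out[name] = {"dice": dices, "pixel_error_pct": errors}
    return out


def aggregate_group(examinations: list[dict], group_labels: list[str],
                    ) -> list[SegMetrics]:
    """Mean ± SD across all slices of all examinations, per group and class.

    ``examinations`` are :func:`evaluate_examination` outputs; SD is the
    population standard deviation of the pooled per-slice values.
    """
    if len(examinations) != len(group_labels):
        raise ValueError("one group label per examination required")
    if not examinations:
        raise ValueError("no examinations to aggregate")
    rows = []
    for group in dict.fromkeys(group_labels):  # stable unique order
        members = [e for e, g in zip(examinations, group_labels) if g == group]
        for cls in (SAT, VAT):
            name = CLASS_NAMES[cls]
            dices = np.concatenate([np.asarray(m[name]["dice"], dtype=float)
                                    for m in members] or [np.array([])])
            errs = np.concatenate(
                [np.asarray(m[name]["pixel_error_pct"], dtype=float)
                 for m in members] or [np.array([])])
            if errs.size == 0:
                raise ValueError(f"group {group!r} has no scored slices "
                                 f"for class {name}")
            rows.append(SegMetrics(
                group=group, compartment=name,
                dice_mean=float(np.mean(dices)) if dices.size else float("nan"),
                dice_sd=float(np.std(dices)) if dices.size else float("nan"),
                pixel_error_mean_pct=float(np.mean(errs)),
                pixel_error_sd_pct=float(np.std(errs)),
                n_slices=int(errs.size), n_examinations=len(members)))
    return rows
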