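"""Volumetric fat quantification and group-level statistics.

Volumes are voxel counts times the voxel volume, reported in mL; the
biomarker readout is the VAT/SAT volume ratio.  Group comparisons use
the classical two-tailed Student's (equal-variance) t-test with the
0.05 significance threshold, method agreement uses the Pearson
correlation of per-subject volumes, computed per group.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .core import SAT, VAT, CohortManifest, FatVolumes, LabelMap

__all__ = ["fat_volumes", "vat_sat_ratio", "ttest_two_tailed", "pearson",
           "GroupStats", "CohortReport", "cohort_report"]

ALPHA = 0.05


def fat_volumes(m: LabelMap, subject_id: str | None = None,
                source: str = "ground_truth") -> FatVolumes:
    """SAT and VAT volumes in mL: voxel counts × dx·dy·dz (mm³) / 1000."""
    if m.spacing is None or any(s <= 0 for s in m.spacing):
        raise ValueError("label map has no valid voxel spacing")
    vox_ml = float(np.prod(m.spacing)) / 1000.0
    return FatVolumes(
        sat_ml=float((m.classes == SAT).sum()) * vox_ml,
        vat_ml=float((m.classes == VAT).sum()) * vox_ml,
        subject_id=subject_id if subject_id is not None else m.subject_id,
        source=source)


def vat_sat_ratio(f: FatVolumes) -> float:
    """VAT/SAT volume ratio; errors when the SAT volume is zero."""
    return f.ratio


def ttest_two_tailed(a, b, equal_var: bool = True) -> tuple[float, float]:
    """Two-sample Student's t-test (two-tailed).

    Welch's unequal-variance variant is available via ``equal_var=False``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 observations")
    if np.var(a, ddof=1) + np.var(b, ddof=1) == 0:
        raise ValueError("zero pooled variance: t statistic undefined")
    t, p = sps.ttest_ind(a, b, equal_var=equal_var)
    return float(t), float(p)


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("need two equal-length samples with n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("Pearson correlation undefined for constant input")
    return float(sps.pearsonr(x, y).statistic)


@dataclass
class GroupStats:
    """Two-group comparison summary (means, SEMs, Student's t, p)."""

    group_a: str
    group_b: str
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    n_a: int
    n_b: int
    t: float
    p: float

    @property
    def significant(self) -> bool:
        return self.p < ALPHA


def _sem(x) -> float:
    x = np.asarray(x, dtype=float)
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


@dataclass
class CohortReport:
    """Per-subject volumes, per-group method agreement, and the group test."""

    volumes: pd.DataFrame                      # one row per subject
    pearson_r: dict[tuple[str, str], float]    # (group, compartment) → r
    ratio_stats: GroupStats
    excluded: list[str] = field(default_factory=list)


def cohort_report(manifest: CohortManifest,
                  predicted: dict[str, LabelMap],
                  reference: dict[str, LabelMap],
                  split: str | None = "test") -> CohortReport:
    """Assemble the group-level analysis over (a split of) a cohort.

    ``predicted`` and ``reference`` map subject ids to label maps.  The
    VAT/SAT ratio contrast (patient vs control) is computed from the
    predicted maps; Pearson r compares predicted against reference
    volumes per group and compartment.
    """
    subjects = manifest.by_split(split) if split else list(manifest.subjects)
    rows, excluded = [], []
    for s in subjects:
        if s.subject_id not in predicted or s.subject_id not in reference:
            excluded.append(s.subject_id)
            continue
        fp = fat_volumes(predicted[s.subject_id], s.subject_id, "predicted")
        fr = fat_volumes(reference[s.subject_id], s.subject_id, "reference")
        rows.append({"subject_id": s.subject_id, "group": s.group,
                     "sat_ml_pred": fp.sat_ml, "vat_ml_pred": fp.vat_ml,
                     "sat_ml_ref": fr.sat_ml, "vat_ml_ref": fr.vat_ml,
                     "ratio_pred": fp.ratio, "ratio_ref": fr.ratio})
    if excluded:
        warnings.warn(f"excluding {len(excluded)} subject(s) with missing "
                      f"maps: {excluded}")
    if not rows:
        raise ValueError("no subjects with both predicted and reference maps")
    df = pd.DataFrame(rows)

    r_values: dict[tuple[str, str], float] = {}
    for group in df["group"].unique():
        sub = df[df["group"] == group]
        for comp, (pc, rc) in {"SAT": ("sat_ml_pred", "sat_ml_ref"),
                               "VAT": ("vat_ml_pred", "vat_ml_ref")}.items():
            if len(sub) >= 3:
                try:
                    r_values[(group, comp)] = pearson(sub[pc], sub[rc])
                except ValueError:
                    r_values[(group, comp)] = float("nan")

    pat = df[df["group"] == "patient"]["ratio_pred"].to_numpy()
    ctl = df[df["group"] == "control"]["ratio_pred"].to_numpy()
    try:
        t, p = ttest_two_tailed(pat, ctl)
    except ValueError as exc:
        warnings.warn(f"ratio contrast degenerate ({exc}); reporting NaN")
        t, p = float("nan"), float("nan")
    stats = GroupStats(group_a="patient", group_b="control",
                       mean_a=float(pat.mean()), mean_b=float(ctl.mean()),
                       sem_a=_sem(pat), sem_b=_sem(ctl),
                       n_a=len(pat), n_b=len(ctl), t=t, p=p)
    return CohortReport(volumes=df, pearson_r=r_values, ratio_stats=stats,
                        excluded=excluded)
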