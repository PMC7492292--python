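"""Per-vertebra bone-marrow-fat quantification from fat-fraction maps.

For each retained ROI the mean of the fat-fraction map is taken slice by
slice; the per-body BMF is the *unweighted* mean of those slice means (each
slice contributes equally, regardless of its pixel count).  Non-finite
fat-fraction pixels — possible after division by near-zero total signal —
are excluded from slice means and counted in the report.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .io_dixon import DixonSeries
from .roi import LUMBAR_LEVELS, VertebraROISet


@dataclass
class SliceMean:
    slice_idx: int
    mean_ff_pct: float
    n_pixels: int
    n_nonfinite: int = 0


@dataclass
class LevelBMF:
    level: str
    mean_bmf_pct: float
    slice_means: list[SliceMean]

    @property
    def n_slices_used(self) -> int:
        return len(self.slice_means)


@dataclass
class BMFReport:
    """Per-subject BMF fractions per lumbar level, with slice provenance."""

    subject_id: str
    levels: dict[str, LevelBMF] = field(default_factory=dict)

    def mean_bmf(self, level: str) -> float:
        return self.levels[level].mean_bmf_pct

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": self.subject_id,
                "level": lv.level,
                "mean_bmf_pct": lv.mean_bmf_pct,
                "n_slices_used": lv.n_slices_used,
            }
            for lv in self.levels.values()
        ]
        return pd.DataFrame(rows, columns=["subject", "level", "mean_bmf_pct", "n_slices_used"])

    def to_long_frame(self) -> pd.DataFrame:
        rows = [
            {
                "subject": self.subject_id,
                "level": lv.level,
                "slice": sm.slice_idx,
                "mean_ff_pct": sm.mean_ff_pct,
                "n_pixels": sm.n_pixels,
                "n_nonfinite": sm.n_nonfinite,
            }
            for lv in self.levels.values()
            for sm in lv.slice_means
        ]
        return pd.DataFrame(
            rows, columns=["subject", "level", "slice", "mean_ff_pct", "n_pixels", "n_nonfinite"]
        )


def slice_mean_ff(ff_slice: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> tuple[float, int]:
    """Arithmetic mean of the fat-fraction map over one component's pixels."""
    if len(rows) == 0:
        raise ValidationError("empty pixel set; callers must pre-filter")
    vals = np.asarray(ff_slice, dtype=np.float64)[rows, cols]
    finite = np.isfinite(vals)
    if not finite.any():
        raise ValidationError("no finite fat-fraction values in pixel set")
    return float(vals[finite].mean()), int(finite.sum())


def vertebra_mean_bmf(slice_means: list[float]) -> float:
    """Unweighted mean of per-slice means: each slice counts equally."""
    if not slice_means:
        raise ValidationError("no retained slices for this level")
    return float(np.mean(slice_means))


def quantify(series: DixonSeries, roiset: VertebraROISet) -> BMFReport:
    """Per-level BMF report over the retained ROI members of ``roiset``."""
    if roiset.shape != series.shape:
        raise ValidationError(
            f"geometry mismatch: roiset {roiset.shape} vs series {series.shape}"
        )
    if not roiset.filtered:
        raise ValidationError("filter the ROI set by area before quantification")
    report = BMFReport(subject_id=series.subject_id)
    ff = series.fat_fraction
    for level in LUMBAR_LEVELS:
        members = roiset.retained_members(level)
        if not members:
            continue  # level absent from the report, by contract
        slice_means = []
        for c in sorted(members, key=lambda m: m.slice_idx):
            vals = np.asarray(ff[c.slice_idx], dtype=np.float64)[c.rows, c.cols]
            finite = np.isfinite(vals)
            mean = float(vals[finite].mean())
            slice_means.append(
                SliceMean(
                    slice_idx=c.slice_idx,
                    mean_ff_pct=mean,
                    n_pixels=int(finite.sum()),
                    n_nonfinite=int((~finite).sum()),
                )
            )
        report.levels[level] = LevelBMF(
            level=level,
            mean_bmf_pct=vertebra_mean_bmf([sm.mean_ff_pct for sm in slice_means]),
            slice_means=slice_means,
        )
    return report
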