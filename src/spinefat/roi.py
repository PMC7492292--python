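"""Connected-component ROI extraction, vertebral level assignment, and the
half-area inclusion rule.

A binary mask volume is decomposed into per-slice 8-connected components;
components are linked across slices into body "tracks" by centroid proximity;
the five largest interior tracks are labelled L1-L5 in superior-to-inferior
order, while tracks touching the superior/inferior image border (partially
imaged T12 or sacrum) are labelled and excluded.  For each level, only the
slices whose component area exceeds half of that body's maximum
cross-sectional area are retained for fat quantification.

The reference area for the half-area rule is the per-body maximum over
slices — the most stable per-body proxy when only the mask is available; the
comparison is strict (``area > 0.5 * reference``).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import ValidationError
from .io_dixon import MaskVolume
from .phantom import LEVEL_CODES

LUMBAR_LEVELS = ("L1", "L2", "L3", "L4", "L5")


@dataclass
class Component:
    """One connected component on one slice."""

    slice_idx: int
    rows: np.ndarray
    cols: np.ndarray
    level: str = "unassigned"
    retained: bool = False
    track_id: int = -1

    @property
    def area(self) -> int:
        return len(self.rows)

    @property
    def centroid(self) -> tuple[float, float]:
        return float(self.rows.mean()), float(self.cols.mean())


@dataclass
class VertebraROISet:
    """All components of a mask volume plus level assignments."""

    shape: tuple[int, int, int]
    components: list[Component] = field(default_factory=list)
    labels_assigned: bool = False
    filtered: bool = False

    def by_slice(self, slice_idx: int) -> list[Component]:
        return [c for c in self.components if c.slice_idx == slice_idx]

    def by_level(self, level: str) -> list[Component]:
        return [c for c in self.components if c.level == level]

    @property
    def levels_present(self) -> list[str]:
        return [lv for lv in LUMBAR_LEVELS if any(c.level == lv for c in self.components)]

    def reference_area(self, level: str) -> int:
        comps = self.by_level(level)
        return max((c.area for c in comps), default=0)

    def retained_members(self, level: str) -> list[Component]:
        return [c for c in self.by_level(level) if c.retained]

    def to_records(self) -> list[dict]:
        out = []
        for c in self.components:
            r, col = c.centroid
            out.append(
                {
                    "slice": c.slice_idx,
                    "level": c.level,
                    "area_px": c.area,
                    "centroid_row": round(r, 2),
                    "centroid_col": round(col, 2),
                    "retained": "yes" if c.retained else "no",
                }
            )
        return out

    def labeled_volume(self) -> np.ndarray:
        """Level-coded volume (1-5 = L1-L5, 11 = T12, 12 = S1)."""
        vol = np.zeros(self.shape, dtype=np.int16)
        for c in self.components:
            code = LEVEL_CODES.get(c.level, 0)
            vol[c.slice_idx, c.rows, c.cols] = code
        return vol


def extract_components(mask: MaskVolume, min_area_px: int = 20) -> VertebraROISet:
    """Per-slice 8-connected component labelling, discarding speckle.

    Components smaller than ``min_area_px`` pixels are treated as
    binarisation noise and dropped.
    """
    if mask.kind != "binary":
        raise ValidationError("binarize first: components require a binary mask")
    structure = ndimage.generate_binary_structure(2, 2)  # 8-connectivity
    roiset = VertebraROISet(shape=mask.shape)
    for s in range(mask.shape[0]):
        labels, n = ndimage.label(mask.data[s], structure=structure)
        for lab in range(1, n + 1):
            rows, cols = np.nonzero(labels == lab)
            if len(rows) < min_area_px:
                continue
            roiset.components.append(Component(slice_idx=s, rows=rows, cols=cols))
    return roiset


def _build_tracks(roiset: VertebraROISet, match_radius_px: float) -> dict[int, list[Component]]:
    """Greedy nearest-centroid linking of components across slices."""
    tracks: dict[int, list[Component]] = {}
    next_id = 0
    for s in range(roiset.shape[0]):
        comps = sorted(roiset.by_slice(s), key=lambda c: c.centroid)
        open_tracks = []
        for tid, members in tracks.items():
            last = members[-1]
            if s - last.slice_idx == 1:
                open_tracks.append((tid, last.centroid))
        taken = set()
        for c in comps:
            cr, cc = c.centroid
            best_tid, best_d = -1, np.inf
            for tid, (tr, tc) in open_tracks:
                if tid in taken:
                    continue
                d = np.hypot(cr - tr, cc - tc)
                if d < best_d:
                    best_tid, best_d = tid, d
            if best_tid >= 0 and best_d <= match_radius_px:
                c.track_id = best_tid
                tracks[best_tid].append(c)
                taken.add(best_tid)
            else:
                c.track_id = next_id
                tracks[next_id] = [c]
                next_id += 1
    return tracks


def assign_vertebra_labels(
    roiset: VertebraROISet, match_radius_px: float = 15.0
) -> VertebraROISet:
    """Assign anatomical levels L1-L5 (and excluded T12/S1) to tracks.

    Tracks with any component touching the superior (row 0) or inferior
    (last row) image border are partially imaged adjacent bodies: the ones in
    the upper half of the image are labelled T12, lower half S1, and they are
    excluded from quantification.  Of the interior tracks, the five with the
    largest peak area are labelled L1-L5 in superior-to-inferior order.
    """
    n_rows = roiset.shape[1]
    tracks = _build_tracks(roiset, match_radius_px)

    border, interior = [], []
    for tid, members in tracks.items():
        touches = any(
            (c.rows.min() == 0) or (c.rows.max() == n_rows - 1) for c in members
        )
        peak = max(c.area for c in members)
        mean_row = float(np.mean([c.centroid[0] for c in members]))
        (border if touches else interior).append((tid, peak, mean_row))

    for tid, _, mean_row in border:
        level = "T12" if mean_row < n_rows / 2 else "S1"
        for c in tracks[tid]:
            c.level = level

    interior.sort(key=lambda t: -t[1])  # by peak area, descending
    chosen = interior[:5]
    if len(chosen) < 5:
        warnings.warn(
            f"insufficient vertebrae detected: {len(chosen)} interior track(s); "
            "labelling top-down",
            stacklevel=2,
        )
    chosen.sort(key=lambda t: t[2])  # superior -> inferior
    for i, (tid, _, _) in enumerate(chosen):
        for c in tracks[tid]:
            c.level = LUMBAR_LEVELS[i]

    roiset.labels_assigned = True
    return roiset


def filter_rois_by_area(roiset: VertebraROISet) -> VertebraROISet:
    """Retain, per level, only slices covering more than half the body's area.

    The reference is the maximum component area over all slices of that
    level; a member is retained iff ``area > 0.5 * reference`` (strict).
    T12/S1 and unassigned components are never retained.
    """
    if not roiset.labels_assigned:
        raise ValidationError("assign levels before filtering")
    for c in roiset.components:
        c.retained = False
    for level in LUMBAR_LEVELS:
        comps = roiset.by_level(level)
        if not comps:
            continue
        reference = max(c.area for c in comps)
        for c in comps:
            c.retained = c.area > 0.5 * reference
    roiset.filtered = True
    return roiset
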