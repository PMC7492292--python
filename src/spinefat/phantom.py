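"""Synthetic sagittal spine phantoms with voxel-accurate ground truth.

The generator emulates the data model of an IDEAL water-fat acquisition: four
co-registered channels (water, fat, fat-fraction in percent, R2* in 1/s) over
a stack of sagittal slices, with a lordotic column of rounded-rectangular
lumbar vertebral bodies visible on a contiguous block of mid-sagittal slices.
Each body carries a dark cortical rim (excluded from the ground-truth mask, as
manual raters contour marrow up to but not including cortical bone) and a
known, noise-free trabecular fat fraction, so downstream quantification can be
checked against exact truth.

Confounder structures — a high-fat subcutaneous band, low-fat paraspinal
muscle, and intermediate-fat intervertebral discs — make segmentation
non-trivial.  Channel synthesis is algebraically faithful to a two-species
decomposition: ``fat = S*FF/100``, ``water = S*(1-FF/100)`` for a smooth
intensity field ``S``; Gaussian noise is added to the water and fat channels
independently and the fat-fraction map is then *recomputed* from the noisy
channels (preserving the ratio coupling of the real reconstruction) and
clipped to [0, 100].
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import ndimage

from .errors import DegenerateMaskError, ValidationError
from .io_dixon import DixonSeries, MaskVolume

#: level encoding used in labelled volumes (matches the ROI export convention)
LEVEL_CODES = {"L1": 1, "L2": 2, "L3": 3, "L4": 4, "L5": 5, "T12": 11, "S1": 12}
CODE_LEVELS = {v: k for k, v in LEVEL_CODES.items()}


@dataclass
class PhantomSpec:
    """Parameters of one synthetic subject.

    Defaults mirror the acquisition geometry the pipeline targets: 20 sagittal
    slices of 256x256 pixels, five lumbar bodies visible on 5-7 mid-sagittal
    slices, and a population mean marrow fat fraction of 33.1%.
    """

    n_slices: int = 20
    image_size: int = 256
    n_vertebrae: int = 5
    visible_slice_range: tuple[int, int] = (5, 7)
    ff_mean_pct: float = 33.1
    ff_sd_pct: float = 8.0
    ff_heterogeneity_pct: float = 2.0
    noise_sd: float = 0.05
    cortical_rim_px: int = 2
    include_t12_sacrum: bool = False
    lordosis_curvature: float = 0.25
    body_height_frac: float = 0.142   # body height / image size
    body_halfwidth_frac: float = 0.085  # body half-width / image size
    seed: int = 0

    def validate(self) -> None:
        lo, hi = self.visible_slice_range
        if not (1 <= lo <= hi <= self.n_slices):
            raise ValidationError("visible_slice_range must lie within [1, n_slices]")
        if not (0 <= self.ff_mean_pct - 3 * self.ff_sd_pct
                and self.ff_mean_pct + 3 * self.ff_sd_pct <= 100):
            raise ValidationError("ff_mean_pct +/- 3*ff_sd_pct must lie within [0, 100]")
        if self.n_vertebrae < 1 or self.image_size < 32 or self.n_slices < 1:
            raise ValidationError("degenerate phantom geometry")
        if self.noise_sd < 0 or self.ff_heterogeneity_pct < 0:
            raise ValidationError("noise parameters must be nonnegative")


@dataclass
class GroundTruth:
    """Voxel-accurate truth for one phantom.

    ``level_map`` encodes anatomical levels per voxel (0 = background,
    1-5 = L1-L5, 11 = T12, 12 = S1); the binary ground-truth mask covers all
    rim-excluded vertebral bodies.  ``true_ff_pct`` maps each level to the
    noise-free trabecular fat fraction assigned to that body.
    """

    level_map: np.ndarray
    true_ff_pct: dict[str, float]

    @property
    def mask(self) -> MaskVolume:
        return MaskVolume((self.level_map > 0).astype(np.uint8), kind="binary")

    def level_mask(self, level: str) -> np.ndarray:
        return self.level_map == LEVEL_CODES[level]

    @property
    def lumbar_levels(self) -> list[str]:
        return [lv for lv in ("L1", "L2", "L3", "L4", "L5") if lv in self.true_ff_pct]


# ---------------------------------------------------------------------------
# geometry helpers
# ---------------------------------------------------------------------------

def _superellipse(rows: np.ndarray, cols: np.ndarray, rc: float, cc: float,
                  a: float, b: float, power: float = 4.0) -> np.ndarray:
    """Rounded-rectangle indicator |(r-rc)/a|^p + |(c-cc)/b|^p <= 1."""
    if a <= 0 or b <= 0:
        return np.zeros(rows.shape, dtype=bool)
    return (np.abs((rows - rc) / a) ** power + np.abs((cols - cc) / b) ** power) <= 1.0


def _smooth_field(rng: np.random.Generator, shape: tuple[int, ...], sigma: float) -> np.ndarray:
    """Zero-mean, unit-SD smooth Gaussian random field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    sd = f.std()
    return f / sd if sd > 0 else f


# ---------------------------------------------------------------------------
# phantom synthesis
# ---------------------------------------------------------------------------

def _truncated_normal(rng: np.random.Generator, mean: float, sd: float,
                      lo: float, hi: float) -> float:
    """One draw from Normal(mean, sd) truncated to [lo, hi] by redraw."""
    if sd == 0:
        return float(np.clip(mean, lo, hi))
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    return float(np.clip(mean, lo, hi))


def generate_phantom(
    spec: PhantomSpec, noise_seed: int | None = None
) -> tuple[DixonSeries, GroundTruth]:
    """Generate one synthetic Dixon series with ground truth.

    Deterministic for a fixed ``spec`` (the anatomy and the noise both derive
    from ``spec.seed``).  Passing ``noise_seed`` re-realises the measurement
    noise while keeping the anatomy and true fat fractions fixed — the
    test-retest regime.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    N = spec.image_size
    n_slices = spec.n_slices
    nv = spec.n_vertebrae

    # ---- column geometry -------------------------------------------------
    margin = 0.06 * N
    usable = N - 2 * margin
    gap_frac = 0.30
    # body height, capped so the whole column always fits inside the margins
    h = min(spec.body_height_frac * N, usable / (nv + (nv - 1) * gap_frac))
    gap = gap_frac * h
    half_h = h / 2.0
    half_w = spec.body_halfwidth_frac * N

    centers_r = [margin + half_h + i * (h + gap) for i in range(nv)]
    mid_r = 0.5 * (centers_r[0] + centers_r[-1])

    def col_center(r: float) -> float:
        # lordotic bow: anterior (lower column index) displacement mid-column
        t = (r - mid_r) / (0.5 * usable)
        return 0.42 * N - spec.lordosis_curvature * 0.15 * N * (1.0 - t * t)

    levels = [f"L{i+1}" for i in range(nv)]
    bodies: list[tuple[str, float, float]] = [
        (lv, centers_r[i], col_center(centers_r[i])) for i, lv in enumerate(levels)
    ]
    if spec.include_t12_sacrum:
        # partially visible adjacent bodies, clipped by the image border
        r_t12 = centers_r[0] - 0.75 * (h + gap)
        r_s1 = centers_r[-1] + 0.75 * (h + gap)
        bodies.append(("T12", r_t12, col_center(max(r_t12, 0.0))))
        bodies.append(("S1", r_s1, col_center(min(r_s1, N - 1.0))))

    # ---- per-body true fat fraction --------------------------------------
    true_ff: dict[str, float] = {
        lv: _truncated_normal(rng, spec.ff_mean_pct, spec.ff_sd_pct, 5.0, 70.0)
        for lv, _, _ in bodies
    }

    # ---- visible slice block ---------------------------------------------
    lo, hi = spec.visible_slice_range
    k = int(rng.integers(lo, hi + 1))
    k = min(k, n_slices)
    s0 = (n_slices - k) // 2
    visible = list(range(s0, s0 + k))

    rows = np.arange(N, dtype=np.float64)[:, None]
    cols = np.arange(N, dtype=np.float64)[None, :]

    # ---- tissue maps, slice by slice -------------------------------------
    ff = np.zeros((n_slices, N, N))
    level_map = np.zeros((n_slices, N, N), dtype=np.int16)
    S = np.ones((n_slices, N, N))
    r2s = np.full((n_slices, N, N), 30.0)

    # smooth fields shared across structures (anatomy rng)
    shading = 1.0 + 0.15 * _smooth_field(rng, (n_slices, N, N), sigma=(1, N / 8, N / 8))
    shading = np.clip(shading, 0.5, 1.5)
    het = _smooth_field(rng, (n_slices, N, N), sigma=(1, 2, 2))

    # static posterior structures (span all slices)
    muscle_lo, muscle_hi = 0.60 * N, 0.78 * N
    fatband_lo, fatband_hi = 0.80 * N, 0.95 * N
    muscle = (cols >= muscle_lo) & (cols < muscle_hi) & (rows >= margin) & (rows < N - margin)
    fatband = (cols >= fatband_lo) & (cols < fatband_hi) & (rows >= margin) & (rows < N - margin)

    for s in range(n_slices):
        ff_s = np.zeros((N, N))
        tissue = np.zeros((N, N), dtype=bool)

        ff_s[muscle] = 8.0
        tissue |= muscle
        ff_s[fatband] = 90.0
        tissue |= fatband
        r2s[s][muscle] = 40.0
        r2s[s][fatband] = 60.0

        if s in visible:
            # elliptical through-slice profile: bodies shrink toward the
            # lateral-most visible slices, so edge slices can fall below the
            # half-area inclusion rule
            u = 2.0 * (s - (s0 + (k - 1) / 2.0)) / (k + 1)
            scale = 0.62 + 0.38 * np.sqrt(max(0.0, 1.0 - u * u))

            for lv, rc, cc in bodies:
                a_out, b_out = half_h * scale, half_w * scale
                rim = spec.cortical_rim_px
                outer = _superellipse(rows, cols, rc, cc, a_out, b_out)
                inner = _superellipse(rows, cols, rc, cc, a_out - rim, b_out - rim)
                rim_px = outer & ~inner
                if not inner.any():
                    continue
                # cortical rim: low signal, low fat
                ff_s[rim_px] = 5.0
                r2s[s][rim_px] = 120.0
                S[s][rim_px] = 0.55
                # trabecular interior: the known fat fraction
                interior_ff = true_ff[lv]
                if spec.ff_heterogeneity_pct > 0:
                    ff_s[inner] = np.clip(
                        interior_ff + spec.ff_heterogeneity_pct * het[s][inner], 0.0, 100.0
                    )
                else:
                    ff_s[inner] = interior_ff
                r2s[s][inner] = 150.0
                level_map[s][inner] = LEVEL_CODES[lv]
                tissue |= outer

            # intervertebral discs between consecutive lumbar bodies
            for i in range(nv - 1):
                rc = 0.5 * (centers_r[i] + centers_r[i + 1])
                disc = _superellipse(rows, cols, rc, col_center(rc),
                                     0.45 * gap * scale, 0.9 * half_w * scale)
                disc &= level_map[s] == 0
                ff_s[disc] = 15.0
                r2s[s][disc] = 35.0
                tissue |= disc

        S[s] = np.where(tissue | (level_map[s] > 0), S[s] * shading[s], 0.04)
        ff[s] = np.where(tissue | (level_map[s] > 0), ff_s, 0.0)

    # ---- channel synthesis ------------------------------------------------
    fat = S * ff / 100.0
    water = S * (1.0 - ff / 100.0)

    if spec.noise_sd > 0:
        tissue_mean = S[S > 0.1].mean() if (S > 0.1).any() else 1.0
        sigma = spec.noise_sd * tissue_mean
        # noise stream kept independent of the anatomy stream
        noise_rng = np.random.default_rng(
            [spec.seed if noise_seed is None else noise_seed, 1]
        )
        water = water + noise_rng.normal(0.0, sigma, water.shape)
        fat = fat + noise_rng.normal(0.0, sigma, fat.shape)
        water = np.clip(water, 0.0, None)
        fat = np.clip(fat, 0.0, None)
        total = water + fat
        with np.errstate(invalid="ignore", divide="ignore"):
            ff_map = np.where(total > 0, 100.0 * fat / total, 0.0)
        ff_map = np.clip(ff_map, 0.0, 100.0)
    else:
        ff_map = ff.copy()

    r2s = np.clip(r2s + 10.0 * _smooth_field(rng, (n_slices, N, N), sigma=(1, 4, 4)), 1.0, None)

    series = DixonSeries(
        subject_id=f"phantom-{spec.seed}",
        water=water,
        fat=fat,
        fat_fraction=ff_map,
        r2star=r2s,
    )
    truth = GroundTruth(level_map=level_map, true_ff_pct=true_ff)
    return series, truth


# ---------------------------------------------------------------------------
# cohorts
# ---------------------------------------------------------------------------

#: default across-subject variation of anatomical parameters
DEFAULT_COHORT_DISTRIBUTION: dict[str, tuple[float, float]] = {
    "ff_mean_pct": (26.0, 40.0),
    "lordosis_curvature": (0.10, 0.40),
    "body_height_frac": (0.128, 0.156),
    "body_halfwidth_frac": (0.075, 0.095),
}


def _subject_spec(base: PhantomSpec, distribution: Mapping[str, tuple[float, float]],
                  rng: np.random.Generator, seed: int) -> PhantomSpec:
    overrides = {k: float(rng.uniform(lo, hi)) for k, (lo, hi) in distribution.items()}
    return dataclasses.replace(base, seed=seed, **overrides)


def generate_cohort(
    n_subjects: int,
    spec: PhantomSpec | None = None,
    spec_distribution: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[tuple[DixonSeries, GroundTruth]]:
    """Generate a cohort of phantoms with across-subject anatomical variation.

    Per-subject seeds derive deterministically from ``seed``; parameters named
    in ``spec_distribution`` are drawn uniformly from the given ranges
    (defaults in :data:`DEFAULT_COHORT_DISTRIBUTION`).
    """
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    base = spec or PhantomSpec()
    distribution = DEFAULT_COHORT_DISTRIBUTION if spec_distribution is None else spec_distribution
    master = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        sub_seed = int(master.integers(0, 2**31 - 1))
        sub_spec = _subject_spec(base, distribution, master, sub_seed)
        series, truth = generate_phantom(sub_spec)
        series.subject_id = f"subject-{i:03d}"
        out.append((series, truth))
    return out


def generate_test_retest(
    n_subjects: int,
    spec: PhantomSpec | None = None,
    spec_distribution: Mapping[str, tuple[float, float]] | None = None,
    seed: int = 0,
) -> list[tuple[tuple[DixonSeries, GroundTruth], tuple[DixonSeries, GroundTruth]]]:
    """Paired scans per subject: identical anatomy, fresh noise realisation."""
    if n_subjects < 1:
        raise ValidationError("n_subjects must be >= 1")
    base = spec or PhantomSpec()
    distribution = DEFAULT_COHORT_DISTRIBUTION if spec_distribution is None else spec_distribution
    master = np.random.default_rng(seed)
    out = []
    for i in range(n_subjects):
        sub_seed = int(master.integers(0, 2**31 - 1))
        retest_noise_seed = int(master.integers(0, 2**31 - 1))
        sub_spec = _subject_spec(base, distribution, master, sub_seed)
        test = generate_phantom(sub_spec)
        retest = generate_phantom(sub_spec, noise_seed=retest_noise_seed)
        test[0].subject_id = f"subject-{i:03d}"
        retest[0].subject_id = f"subject-{i:03d}"
        out.append((test, retest))
    return out


# ---------------------------------------------------------------------------
# simulated raters
# ---------------------------------------------------------------------------

def simulate_rater(
    truth: GroundTruth,
    bias_px: int = 0,
    boundary_jitter_px: float = 0.0,
    seed: int = 0,
) -> MaskVolume:
    """Emulate a human rater: systematic over/under-contouring plus jitter.

    ``bias_px > 0`` dilates every component by that many pixels, ``< 0``
    erodes; ``boundary_jitter_px`` perturbs the contour by a smooth seeded
    random displacement of the signed distance to the boundary.
    """
    base = truth.mask.data.astype(bool)
    body_labels, n_truth = ndimage.label(base, structure=np.ones((3, 3, 3)))
    out = np.zeros_like(base)
    structure = ndimage.generate_binary_structure(2, 2)
    rng = np.random.default_rng(seed)
    for s in range(base.shape[0]):
        m = base[s]
        if not m.any():
            continue
        if bias_px > 0:
            m = ndimage.binary_dilation(m, structure=structure, iterations=bias_px)
        elif bias_px < 0:
            m = ndimage.binary_erosion(m, structure=structure, iterations=-bias_px)
        if boundary_jitter_px > 0 and m.any():
            inside = ndimage.distance_transform_edt(m)
            outside = ndimage.distance_transform_edt(~m)
            sdist = inside - outside
            jitter = boundary_jitter_px * _smooth_field(rng, m.shape, sigma=3.0)
            m = (sdist + jitter) > 0
        out[s] = m
    survived = np.unique(body_labels[out & base])
    lost = n_truth - int((survived > 0).sum())
    if lost > 0:
        raise DegenerateMaskError(
            f"degenerate rater mask: {lost} component(s) annihilated"
        )
    return MaskVolume(out.astype(np.uint8), kind="binary")
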