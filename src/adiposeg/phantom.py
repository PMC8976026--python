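"""Synthetic abdominal T1w-like phantom cohorts with known SAT/VAT truth.

Each phantom slice is an elliptical body cross-section: a bright
subcutaneous fat (SAT) annulus just inside the skin, a mid-intensity
"organ" cavity, bright visceral fat (VAT) blobs inside the cavity, and —
optionally — bone confounders (dark marrow core with a bright, fat-like
cortical rim) near the spine and the hips, which are labelled background
on purpose so that intensity-driven methods can reproduce the classic
hip-bone-as-VAT failure mode.  Volumes are corrupted by a smooth
second-order polynomial bias field and Rician noise, the two nuisance
processes of magnitude MRI; the ground-truth label map is noise-free.

A two-group cohort (control vs patient) carries an injected VAT/SAT-ratio
effect: patients draw a higher visceral fat fraction and a thinner
subcutaneous layer.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import ndimage

from .core import BACKGROUND, SAT, VAT, CohortManifest, LabelMap, SubjectRecord, VolumeImage
from . import io as aio

__all__ = [
    "PhantomSubject",
    "PhantomGroupConfig",
    "StationSeries",
    "sample_subject",
    "render_volume",
    "split_into_stations",
    "generate_cohort",
    "default_group_configs",
    "desk_group_configs",
    "DESK_DIMS",
    "DESK_SPACING",
]

# Intensity constants (arbitrary units, T1w-like contrast: fat hyperintense).
FAT_INTENSITY = 200.0
ORGAN_INTENSITY = 100.0
BONE_CORE_INTENSITY = 40.0
BONE_RIM_INTENSITY = 190.0  # deliberately fat-like: the confounder
BACKGROUND_INTENSITY = 0.0

#: desk-scale grid used by the package's own experiments: 64×64 in-plane at
#: 3 mm (192 mm field of view) keeps abdominal geometry plausible while the
#: protocol-faithful grid stays available via ``render_volume`` arguments.
DESK_DIMS = (64, 64, 12)
DESK_SPACING = (3.0, 3.0, 6.0)

PROTOCOL_DIMS = (384, 384, 36)
PROTOCOL_SPACING = (1.25, 1.25, 6.0)


@dataclass
class PhantomSubject:
    """Generative parameters of one synthetic subject."""

    subject_id: str
    group: str                      # "control" | "patient"
    body_ax: float = 150.0          # body semi-axis, x (mm)
    body_ay: float = 110.0          # body semi-axis, y (mm)
    sat_thickness: float = 20.0     # subcutaneous annulus width (mm)
    vat_fraction: float = 0.2       # target fraction of cavity area that is VAT
    n_vat_blobs: int = 5
    bone_flag: bool = True
    bias_amplitude: float = 0.15    # relative multiplicative field strength
    noise_sigma: float = 0.04      # Rician sigma relative to fat intensity
    rng_seed: int = 0
    age: float = 55.0
    bmi: float = 24.0

    def __post_init__(self) -> None:
        if self.sat_thickness <= 0:
            raise ValueError("sat_thickness must be > 0")
        if not 0 <= self.vat_fraction < 1:
            raise ValueError("vat_fraction must be in [0, 1)")
        if self.bias_amplitude < 0 or self.noise_sigma < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 <= self.bias_amplitude <= 0.5:
            raise ValueError("bias_amplitude must be in [0, 0.5]")


@dataclass
class PhantomGroupConfig:
    """Per-group sampling distributions (all truncated to subject invariants)."""

    group: str
    n_subjects: int
    base_seed: int
    sat_thickness_mean: float
    sat_thickness_sd: float
    vat_fraction_mean: float
    vat_fraction_sd: float
    body_ax_mean: float = 150.0
    body_ax_sd: float = 12.0
    body_ay_mean: float = 110.0
    body_ay_sd: float = 10.0
    age_mean: float = 55.0
    age_sd: float = 10.0
    bmi_mean: float = 24.0
    bmi_sd: float = 3.0
    n_vat_blobs: int = 5
    bone_flag: bool = True
    bias_amplitude: float = 0.15
    noise_sigma: float = 0.04


_GROUP_CODE = {"control": 1, "patient": 2}


def default_group_configs(base_seed: int = 0, n_subjects: int = 34,
                          ) -> tuple[PhantomGroupConfig, PhantomGroupConfig]:
    """Protocol-scale cohort: patients carry a higher VAT fraction and a
    thinner SAT layer, i.e. an elevated VAT/SAT ratio."""
    control = PhantomGroupConfig(
        group="control", n_subjects=n_subjects, base_seed=base_seed,
        sat_thickness_mean=18.0, sat_thickness_sd=3.0,
        vat_fraction_mean=0.15, vat_fraction_sd=0.05,
        age_mean=55.0, bmi_mean=25.0)
    patient = PhantomGroupConfig(
        group="patient", n_subjects=n_subjects, base_seed=base_seed,
        sat_thickness_mean=15.0, sat_thickness_sd=2.5,
        vat_fraction_mean=0.30, vat_fraction_sd=0.07,
        age_mean=60.0, bmi_mean=23.0)
    return control, patient


def desk_group_configs(base_seed: int = 0, n_subjects: int = 34,
                       ) -> tuple[PhantomGroupConfig, PhantomGroupConfig]:
    """Desk-scale cohort matched to the 192 mm field of view of DESK_DIMS."""
    control, patient = default_group_configs(base_seed, n_subjects)
    small = dict(body_ax_mean=72.0, body_ax_sd=5.0,
                 body_ay_mean=54.0, body_ay_sd=4.0)
    return replace(control, **small), replace(patient, **small)


def _subject_seed(base_seed: int, group: str, index: int) -> int:
    # deterministic, collision-free across (group, index), kept below 2**31
    return int((base_seed * 1_000_003 + _GROUP_CODE[group] * 262_147 + index)
               % (2**31 - 1))


def sample_subject(cfg: PhantomGroupConfig, group: str, index: int) -> PhantomSubject:
    """Draw one subject's generative parameters from the group distributions.

    Deterministic given ``(cfg.base_seed, group, index)``.
    """
    if group not in _GROUP_CODE:
        raise ValueError(f"unknown group {group!r}; expected 'control' or 'patient'")
    if not 0 <= index < cfg.n_subjects:
        raise IndexError(f"subject index {index} out of range [0, {cfg.n_subjects})")
    seed = _subject_seed(cfg.base_seed, group, index)
    rng = np.random.default_rng(seed)
    sat = float(np.clip(rng.normal(cfg.sat_thickness_mean, cfg.sat_thickness_sd),
                        6.0, 45.0))
    vat = float(np.clip(rng.normal(cfg.vat_fraction_mean, cfg.vat_fraction_sd),
                        0.02, 0.60))
    ax = float(np.clip(rng.normal(cfg.body_ax_mean, cfg.body_ax_sd),
                       0.5 * cfg.body_ax_mean, 1.5 * cfg.body_ax_mean))
    ay = float(np.clip(rng.normal(cfg.body_ay_mean, cfg.body_ay_sd),
                       0.5 * cfg.body_ay_mean, 1.5 * cfg.body_ay_mean))
    return PhantomSubject(
        subject_id=f"{group}_{index:03d}",
        group=group, body_ax=ax, body_ay=ay, sat_thickness=sat,
        vat_fraction=vat, n_vat_blobs=cfg.n_vat_blobs, bone_flag=cfg.bone_flag,
        bias_amplitude=cfg.bias_amplitude, noise_sigma=cfg.noise_sigma,
        rng_seed=seed,
        age=float(rng.normal(cfg.age_mean, cfg.age_sd)),
        bmi=float(np.clip(rng.normal(cfg.bmi_mean, cfg.bmi_sd), 15.0, 45.0)),
    )


# ------------------------------------------------------------- rendering

def _ellipse(xx, yy, cx, cy, a, b):
    if a <= 0 or b <= 0:
        return np.zeros(np.broadcast_shapes(xx.shape, yy.shape), dtype=bool)
    return ((xx - cx) / a) ** 2 + ((yy - cy) / b) ** 2 <= 1.0


def render_volume(s: PhantomSubject,
                  dims: tuple[int, int, int] = DESK_DIMS,
                  spacing: tuple[float, float, float] = DESK_SPACING,
                  ) -> tuple[VolumeImage, LabelMap]:
    """Render one subject into an intensity volume and its ground truth.

    The label map is noise-free; bias field and Rician noise corrupt only
    the intensities.  Fully deterministic given the subject (seeded).
    """
    nx, ny, nz = dims
    if nx < 32 or ny < 32 or nz < 8:
        raise ValueError(f"dims {dims} too small; need at least (32, 32, 8)")
    dx, dy, dz = spacing
    rng = np.random.default_rng(s.rng_seed)

    ax_vox, ay_vox = s.body_ax / dx, s.body_ay / dy
    cx, cy = (nx - 1) / 2.0, (ny - 1) / 2.0
    inner_vox = (min(s.body_ax, s.body_ay) - s.sat_thickness) / max(dx, dy)
    if inner_vox < 4 or ax_vox >= nx / 2 or ay_vox >= ny / 2:
        raise ValueError(
            f"body (semi-axes {s.body_ax:.0f}×{s.body_ay:.0f} mm, SAT "
            f"{s.sat_thickness:.0f} mm) does not fit dims {dims} at spacing {spacing}")

    xx, yy = np.ogrid[0:nx, 0:ny]
    intensity = np.zeros(dims, dtype=np.float64)
    labels = np.zeros(dims, dtype=np.uint8)

    zc = (nz - 1) / 2.0
    # smooth waist profile: body narrows towards both volume ends
    prof = 1.0 - 0.12 * ((np.arange(nz) - zc) / max(zc, 1.0)) ** 2

    # 3-D VAT blob parameters are drawn once so the blob set is a function of
    # the seed alone; radii then scale monotonically with vat_fraction.
    # Blobs are z-elongated (visceral fat tracks the mesentery through many
    # slices), so most slices carry some VAT.
    blob_u = rng.uniform(-0.75, 0.75, size=(s.n_vat_blobs, 2))  # in-plane, cavity units
    blob_z = rng.uniform(0.2 * nz, 0.8 * nz, size=s.n_vat_blobs)
    blob_rz = rng.uniform(0.45, 0.9, size=s.n_vat_blobs) * nz
    blob_aspect = rng.uniform(0.7, 1.4, size=s.n_vat_blobs)
    # blobs drift in-plane along z (visceral fat is tortuous); this also
    # gives the volume the through-plane structure that makes z-alignment
    # of stations identifiable
    blob_tilt = rng.uniform(-0.6, 0.6, size=(s.n_vat_blobs, 2))  # voxels/slice

    for k in range(nz):
        a = ax_vox * prof[k]
        b = ay_vox * prof[k]
        body = _ellipse(xx, yy, cx, cy, a, b)
        inner = _ellipse(xx, yy, cx, cy, a - s.sat_thickness / dx,
                         b - s.sat_thickness / dy)
        sat_ring = body & ~inner
        # cavity kept clear of the SAT ring so ground truths never touch
        cav_a = a - s.sat_thickness / dx - 2.0
        cav_b = b - s.sat_thickness / dy - 2.0
        cavity = _ellipse(xx, yy, cx, cy, cav_a, cav_b)

        sl_int = np.full((nx, ny), BACKGROUND_INTENSITY)
        sl_int[inner] = ORGAN_INTENSITY
        sl_int[sat_ring] = FAT_INTENSITY
        sl_lab = np.zeros((nx, ny), dtype=np.uint8)
        sl_lab[sat_ring] = SAT

        # visceral blobs: area budget vat_fraction × cavity area, split evenly
        cav_area = float(cavity.sum())
        vat_mask = np.zeros((nx, ny), dtype=bool)
        if cav_area > 0 and s.vat_fraction > 0:
            r0 = np.sqrt(s.vat_fraction * cav_area / (s.n_vat_blobs * np.pi))
            for j in range(s.n_vat_blobs):
                dzk = (k - blob_z[j]) / blob_rz[j]
                if abs(dzk) >= 1.0:
                    continue
                shrink = np.sqrt(1.0 - dzk**2)  # ellipsoid cross-section
                rj = r0 * shrink
                bcx = cx + blob_u[j, 0] * cav_a + blob_tilt[j, 0] * (k - blob_z[j])
                bcy = cy + blob_u[j, 1] * cav_b + blob_tilt[j, 1] * (k - blob_z[j])
                vat_mask |= _ellipse(xx, yy, bcx, bcy, rj * blob_aspect[j],
                                     rj / blob_aspect[j])
            vat_mask &= cavity
        sl_int[vat_mask] = FAT_INTENSITY
        sl_lab[vat_mask] = VAT

        # bone confounders: spine (all slices) and hip bones (inferior third)
        if s.bone_flag:
            bones = np.zeros((nx, ny), dtype=bool)
            spine_r = 0.10 * min(a, b)
            bones |= _ellipse(xx, yy, cx, cy + 0.55 * cav_b, spine_r, spine_r * 1.2)
            if k < nz // 3:
                hip_r = 0.12 * min(a, b)
                for sgn in (-1, 1):
                    bones |= _ellipse(xx, yy, cx + sgn * 0.62 * cav_a,
                                      cy + 0.30 * cav_b, hip_r, hip_r)
            bones &= cavity
            rim = ndimage.binary_dilation(bones, iterations=1) & cavity & ~bones
            sl_int[bones] = BONE_CORE_INTENSITY
            sl_int[rim] = BONE_RIM_INTENSITY
            # bone is background in the ground truth, even the fat-like rim
            sl_lab[bones | rim] = BACKGROUND

        intensity[:, :, k] = sl_int
        labels[:, :, k] = sl_lab

    # second-order polynomial bias field, zero-mean, unit max amplitude
    if s.bias_amplitude > 0:
        coef = rng.uniform(-1, 1, size=10)
        gx = (np.arange(nx) / nx - 0.5)[:, None, None]
        gy = (np.arange(ny) / ny - 0.5)[None, :, None]
        gz = (np.arange(nz) / nz - 0.5)[None, None, :]
        poly = (coef[0] + coef[1] * gx + coef[2] * gy + coef[3] * gz
                + coef[4] * gx * gy + coef[5] * gx * gz + coef[6] * gy * gz
                + coef[7] * gx**2 + coef[8] * gy**2 + coef[9] * gz**2)
        poly = poly - poly.mean()
        peak = np.abs(poly).max()
        if peak > 0:
            poly /= peak
        intensity = intensity * (1.0 + s.bias_amplitude * poly)

    # Rician noise: magnitude of a complex signal with Gaussian noise
    if s.noise_sigma > 0:
        sig = s.noise_sigma * FAT_INTENSITY
        n1 = rng.normal(0, sig, size=dims)
        n2 = rng.normal(0, sig, size=dims)
        intensity = np.sqrt((intensity + n1) ** 2 + n2**2)

    vol = VolumeImage(data=intensity, spacing=spacing, subject_id=s.subject_id)
    gt = LabelMap(classes=labels, spacing=spacing, subject_id=s.subject_id)
    return vol, gt


# ---------------------------------------------------------- stations

@dataclass
class StationSeries:
    """Ordered multi-station acquisition of one body, inferior→superior."""

    stations: list[VolumeImage]
    overlap_slices: int
    true_shifts: list[tuple[float, float, float]] | None = None
    ground_truth: LabelMap | None = None

    def __post_init__(self) -> None:
        if len(self.stations) < 2:
            raise ValueError("a station series needs at least 2 stations")
        shapes = {st.shape[:2] for st in self.stations}
        spacings = {st.spacing for st in self.stations}
        if len(shapes) != 1 or len(spacings) != 1:
            raise ValueError("stations must share in-plane dims and spacing")


def split_into_stations(v: VolumeImage, gt: LabelMap | None, n_stations: int,
                        overlap_slices: int,
                        true_shifts: list[tuple[float, float, float]] | None = None,
                        ) -> StationSeries:
    """Cut a volume into overlapping stations, translating each upper station
    by its (known) shift to emulate between-station patient motion.

    ``true_shifts`` has one entry per junction and is applied to the
    superior station of that junction; entries are in voxels, each
    component at most 3 in magnitude.
    """
    if not 1 <= overlap_slices <= 3:
        raise ValueError(f"overlap_slices must be 1..3, got {overlap_slices}")
    if n_stations < 2:
        raise ValueError("need at least 2 stations")
    nz = v.shape[2]
    total = nz + (n_stations - 1) * overlap_slices
    if total % n_stations:
        raise ValueError(
            f"{nz} slices cannot be split into {n_stations} equal stations "
            f"with overlap {overlap_slices}")
    length = total // n_stations
    if length <= overlap_slices:
        raise ValueError("stations would exceed volume extent")
    if true_shifts is None:
        true_shifts = [(0.0, 0.0, 0.0)] * (n_stations - 1)
    if len(true_shifts) != n_stations - 1:
        raise ValueError("need one true shift per junction")
    for sh in true_shifts:
        if max(abs(c) for c in sh) > 3:
            raise ValueError(f"shift {sh} exceeds 3 voxels")

    stations = []
    data = v.data.astype(np.float64)
    for i in range(n_stations):
        z0 = i * (length - overlap_slices)
        sh = (0.0, 0.0, 0.0) if i == 0 else true_shifts[i - 1]
        if any(sh):
            # the patient (anatomy) moves, the acquisition slab stays put:
            # shift the whole volume, then crop the station
            moved = ndimage.shift(data, sh, order=1, mode="nearest")
        else:
            moved = data
        block = moved[:, :, z0:z0 + length]
        stations.append(VolumeImage(block, spacing=v.spacing,
                                    origin_z=z0 * v.spacing[2],
                                    subject_id=v.subject_id))
    return StationSeries(stations=stations, overlap_slices=overlap_slices,
                         true_shifts=[tuple(map(float, s)) for s in true_shifts],
                         ground_truth=gt)


# ------------------------------------------------------------- cohort I/O

def generate_cohort(configs: tuple[PhantomGroupConfig, PhantomGroupConfig],
                    out_dir,
                    dims: tuple[int, int, int] = DESK_DIMS,
                    spacing: tuple[float, float, float] = DESK_SPACING,
                    write_png_slices: bool = False,
                    ) -> CohortManifest:
    """Render and write every subject of a two-group cohort.

    Writes ``<id>_vol.nii.gz`` and ``<id>_mask.nii.gz`` per subject plus a
    JSON manifest; optionally per-slice PNG masks under ``<id>_masks/``.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = []
    for cfg in configs:
        for i in range(cfg.n_subjects):
            subj = sample_subject(cfg, cfg.group, i)
            vol, gt = render_volume(subj, dims=dims, spacing=spacing)
            vp = out_dir / f"{subj.subject_id}_vol.nii.gz"
            mp = out_dir / f"{subj.subject_id}_mask.nii.gz"
            aio.write_volume(vol, vp)
            aio.write_labelmap(gt, mp)
            if write_png_slices:
                pdir = out_dir / f"{subj.subject_id}_masks"
                pdir.mkdir(exist_ok=True)
                for k in range(gt.shape[2]):
                    aio.write_mask_png(gt.classes[:, :, k],
                                       pdir / f"slice_{k:03d}.png")
            records.append(SubjectRecord(
                subject_id=subj.subject_id, group=subj.group,
                age=subj.age, bmi=subj.bmi,
                volume_path=str(vp), mask_path=str(mp)))
    manifest = CohortManifest(subjects=records)
    aio.write_manifest(manifest, out_dir / "manifest.json")
    return manifest


def render_cohort_in_memory(configs, dims=DESK_DIMS, spacing=DESK_SPACING):
    """Like :func:`generate_cohort` but returns (record, volume, truth)
    triples without touching disk — used by tests and experiments."""
    out = []
    for cfg in configs:
        for i in range(cfg.n_subjects):
            subj = sample_subject(cfg, cfg.group, i)
            vol, gt = render_volume(subj, dims=dims, spacing=spacing)
            rec = SubjectRecord(subject_id=subj.subject_id, group=subj.group,
                                age=subj.age, bmi=subj.bmi)
            out.append((rec, vol, gt))
    return out
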