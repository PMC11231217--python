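"""Synthetic fixtures: toy dot images and multimodal tumor phantoms.

``make_dots_image`` builds the colored-discs toy used to illustrate the
blocks. ``make_tumor_phantom`` emulates a BraTS-style subject: an
ellipsoidal brain containing nested spherical tumor shells (enhancing
inside core inside whole tumor) rendered in four MRI contrasts — edema
bright in FLAIR/T2, enhancing tumor bright in contrast-enhanced T1 —
plus seeded additive Gaussian noise. Labels use the raw BraTS codes
(0 background, 1 necrotic core, 2 edema, 4 enhancing) so phantoms flow
through the same class mapping as real data.

These phantoms capture region geometry and modality contrast only; they
have none of the anatomy, bias fields or partial-volume effects of real
MRI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .data_io import MODALITIES, VolumeSample, save_nifti, write_manifest

__all__ = ["PhantomSpec", "make_dots_image", "make_tumor_phantom", "write_fixture_dataset"]

# seven distinct disc colors for the toy image
_PALETTE = np.array([
    [0.9, 0.1, 0.1], [0.1, 0.7, 0.1], [0.15, 0.25, 0.9], [0.95, 0.8, 0.1],
    [0.85, 0.15, 0.85], [0.1, 0.8, 0.8], [0.95, 0.55, 0.1],
])

#: per-modality mean intensity of each tissue class (background, brain,
#: necrotic core, edema, enhancing), index by BraTS label where tumorous
_DEFAULT_INTENSITIES = {
    "flair": {"background": 0.02, "brain": 0.30, 1: 0.50, 2: 0.90, 4: 0.60},
    "t1":    {"background": 0.02, "brain": 0.60, 1: 0.25, 2: 0.40, 4: 0.50},
    "t1ce":  {"background": 0.02, "brain": 0.50, 1: 0.20, 2: 0.40, 4: 0.95},
    "t2":    {"background": 0.02, "brain": 0.40, 1: 0.60, 2: 0.85, 4: 0.55},
}


@dataclass(frozen=True)
class PhantomSpec:
    """Parameters of the multimodal tumor phantom generator."""

    shape: tuple = (64, 64, 48)
    brain_axes: tuple = (26.0, 26.0, 19.0)
    tumor_center: tuple | None = None  # defaults to the volume center
    whole_radius: float = 12.0
    core_radius: float = 8.0
    enhancing_radius: float = 4.0
    intensities: dict = field(default_factory=lambda: _DEFAULT_INTENSITIES)
    noise_sd: float = 0.02
    perturbation: float = 0.0  # relative radial surface perturbation amplitude
    seed: int = 0

    def __post_init__(self):
        if not self.enhancing_radius < self.core_radius < self.whole_radius:
            raise ValueError(
                f"radii must be strictly nested: enhancing {self.enhancing_radius} "
                f"< core {self.core_radius} < whole {self.whole_radius}")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.perturbation < 0:
            raise ValueError("perturbation must be >= 0")
        if self.whole_radius * (1 + self.perturbation) >= min(self.brain_axes):
            raise ValueError("whole tumor does not fit inside the brain ellipsoid")

    @property
    def center(self) -> tuple:
        if self.tumor_center is not None:
            return self.tumor_center
        return tuple(s / 2.0 for s in self.shape)


def make_dots_image(n_dots: int, image_size: int = 64, seed: int = 0,
                    radius_range: tuple = (4, 8), max_tries: int = 2000,
                    return_placements: bool = False):
    """Non-overlapping colored discs on a dark background.

    Returns ``(image, mask)`` where image is (H, W, 3) in [0, 1] and mask
    labels the pixels of disc i with value i (background 0); with
    ``return_placements`` also the list of (cy, cx, r) disc centers and
    radii. Raises if the discs cannot be placed without overlap within
    ``max_tries``.
    """
    if n_dots < 1:
        raise ValueError("n_dots must be >= 1")
    rng = np.random.default_rng(seed)
    h = w = int(image_size)
    yy, xx = np.mgrid[0:h, 0:w]
    placed = []  # (cy, cx, r)
    tries = 0
    while len(placed) < n_dots:
        if tries >= max_tries:
            raise RuntimeError(
                f"could not place {n_dots} non-overlapping discs in a "
                f"{h}x{w} image after {max_tries} tries")
        tries += 1
        r = rng.uniform(*radius_range)
        cy = rng.uniform(r + 1, h - r - 1)
        cx = rng.uniform(r + 1, w - r - 1)
        if all((cy - py) ** 2 + (cx - px) ** 2 > (r + pr + 1.5) ** 2
               for py, px, pr in placed):
            placed.append((cy, cx, r))
    image = np.full((h, w, 3), 0.05)
    mask = np.zeros((h, w), dtype=np.int64)
    for i, (cy, cx, r) in enumerate(placed, start=1):
        disc = (yy - cy) ** 2 + (xx - cx) ** 2 <= r**2
        image[disc] = _PALETTE[(i - 1) % len(_PALETTE)]
        mask[disc] = i
    if return_placements:
        return image, mask, placed
    return image, mask


def make_tumor_phantom(spec: PhantomSpec = PhantomSpec(),
                       subject_id: str = "phantom") -> VolumeSample:
    """Render one multimodal phantom subject.

    Labels are exact nested shells: 2 (edema) in whole-minus-core, 1
    (necrotic core) in core-minus-enhancing, 4 (enhancing) inside the
    innermost sphere, 0 elsewhere, so ET ⊆ TC ⊆ WT holds by
    construction. With ``noise_sd == 0`` every voxel equals its tissue
    class mean exactly.
    """
    rng = np.random.default_rng(spec.seed)
    zz, yy, xx = np.meshgrid(*[np.arange(s) + 0.5 for s in spec.shape], indexing="ij")
    cz, cy, cx = spec.center
    az, ay, ax = spec.brain_axes
    brain = ((zz - cz) / az) ** 2 + ((yy - cy) / ay) ** 2 + ((xx - cx) / ax) ** 2 <= 1.0
    r = np.sqrt((zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2)
    if spec.perturbation > 0:
        # low-frequency angular ripple on the tumor surface; seeded
        phase = rng.uniform(0, 2 * np.pi, size=3)
        theta = np.arctan2(yy - cy, xx - cx)
        phi = np.arctan2(zz - cz, r + 1e-9)
        ripple = 1.0 + spec.perturbation * (
            np.sin(3 * theta + phase[0]) * np.cos(2 * phi + phase[1]))
        r = r / ripple
    labels = np.zeros(spec.shape, dtype=np.int64)
    labels[r <= spec.whole_radius] = 2
    labels[r <= spec.core_radius] = 1
    labels[r <= spec.enhancing_radius] = 4
    modalities = {}
    for m in MODALITIES:
        levels = spec.intensities[m]
        vol = np.full(spec.shape, levels["background"])
        vol[brain] = levels["brain"]
        for code in (2, 1, 4):
            vol[labels == code] = levels[code]
        if spec.noise_sd > 0:
            vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.shape)
        modalities[m] = vol
    return VolumeSample(subject_id=subject_id, modalities=modalities, labels=labels)


def write_fixture_dataset(n_subjects: int, spec: PhantomSpec = PhantomSpec(),
                          out_dir=".", jitter: float = 0.15):
    """Write BraTS-style NIfTI fixtures plus a manifest CSV.

    Each subject gets five files (four modalities + segmentation) named
    ``BraTS20_Synthetic_XXX_<modality>.nii``. Subject i uses seed
    ``spec.seed + i`` and radii jittered by up to ``jitter`` relative so
    subjects differ; generation is fully deterministic. Returns the
    manifest path.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rows = []
    for i in range(n_subjects):
        rng = np.random.default_rng(spec.seed + i)
        scale = 1.0 + rng.uniform(-jitter, jitter)
        sub_spec = replace(
            spec,
            seed=spec.seed + i,
            whole_radius=spec.whole_radius * scale,
            core_radius=spec.core_radius * scale,
            enhancing_radius=spec.enhancing_radius * scale,
        )
        sid = f"BraTS20_Synthetic_{i + 1:03d}"
        sample = make_tumor_phantom(sub_spec, subject_id=sid)
        row = {"subject_id": sid}
        for m in MODALITIES:
            fname = f"{sid}_{m}.nii"
            save_nifti(sample.modalities[m].astype(np.float32), out / fname)
            row[m] = fname
        seg_name = f"{sid}_seg.nii"
        save_nifti(sample.labels.astype(np.int16), out / seg_name)
        row["seg"] = seg_name
        rows.append(row)
    manifest = out / "manifest.csv"
    write_manifest(rows, manifest)
    return manifest
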