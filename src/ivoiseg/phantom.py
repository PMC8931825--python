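"""Synthetic mouse-brain cohort with known ground truth.

Emulates a paired-scan small-animal study: each mouse carries one smooth,
invertible anatomical deformation away from a common template and is imaged
twice (baseline BL, follow-up FU).  Per scan the phantom produces a T2-like MR
volume (region contrast + multiplicative bias field + Gaussian noise) and a
co-registered FDG-like PET volume (per-region uptake, session-dependent
treatment effect, Gaussian PSF blur, Gaussian counting noise), together with
the ground-truth brain mask, the warped five-region VOI labels, and the
forward deformation itself.

Anatomy is a coarse geometric mimic of the mouse brain: a brain ellipsoid with
a caudal cap for the cerebellum, a dorsal outer shell for the cortex, and three
interior ellipsoids (hippocampus, striatum, thalamus), all embedded in a larger
soft-tissue "head" ellipsoid that gives skull-stripping something to strip.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .core import BinaryMask, ImageVolume, LabelVolume, REGION_NAMES, save_volume
from .deformation import (
    DisplacementField,
    invert_field,
    jacobian_determinant,
    warp_volume,
)

logger = logging.getLogger(__name__)

BL = "BL"
FU = "FU"

# Tissue codes used internally while painting anatomy: 0 background (air),
# 1..5 the template VOIs, 6 non-VOI brain parenchyma, 7 extracranial head
# tissue.  Brain mask = codes 1..6.
PARENCHYMA = 6
HEAD = 7
_TISSUES = {**REGION_NAMES, PARENCHYMA: "parenchyma", HEAD: "head", 0: "background"}


class PhantomSpecError(ValueError):
    pass


@dataclass(frozen=True)
class Ellipsoid:
    """Axis-aligned ellipsoid in fractional grid coordinates (z, y, x)."""

    center: tuple[float, float, float]
    semi: tuple[float, float, float]

    def inside(self, grid_shape: tuple[int, int, int]) -> np.ndarray:
        coords = np.meshgrid(
            *(np.arange(s, dtype=np.float64) for s in grid_shape), indexing="ij"
        )
        total = np.zeros(grid_shape)
        for dim, coord in enumerate(coords):
            n = grid_shape[dim]
            total += ((coord - self.center[dim] * n) / (self.semi[dim] * n)) ** 2
        return total <= 1.0


def _default_geometry() -> dict:
    return {
        "head": Ellipsoid((0.50, 0.50, 0.50), (0.47, 0.43, 0.45)),
        "brain": Ellipsoid((0.50, 0.50, 0.50), (0.40, 0.33, 0.36)),
        "inner": Ellipsoid((0.50, 0.50, 0.50), (0.29, 0.24, 0.26)),
        "hippocampus": Ellipsoid((0.47, 0.46, 0.42), (0.09, 0.07, 0.08)),
        "striatum": Ellipsoid((0.40, 0.53, 0.56), (0.09, 0.07, 0.08)),
        "thalamus": Ellipsoid((0.60, 0.55, 0.54), (0.09, 0.07, 0.08)),
        # caudal cap: brain voxels with z >= z_split * Z are cerebellum
        "z_split_frac": 0.72,
        # dorsal half: shell voxels with y < y_split * Y are cortex
        "y_split_frac": 0.50,
    }


@dataclass(frozen=True)
class PhantomSpec:
    """All knobs of the synthetic study, with the study defaults baked in.

    Spacing mirrors a 20 mm FOV acquired at 256 and analysed on a 128 grid
    (in-plane 0.15625 mm) with 0.8 mm slices, so mm-valued surface distances
    stay meaningful.
    """

    grid_shape: tuple[int, int, int] = (70, 128, 128)
    spacing_mm: tuple[float, float, float] = (0.8, 0.15625, 0.15625)
    region_geometry: dict = field(default_factory=_default_geometry)
    # T2-like contrast, arbitrary units
    mr_intensity: dict = field(
        default_factory=lambda: {
            "background": 0.0,
            "head": 60.0,
            "parenchyma": 100.0,
            "cortex": 140.0,
            "hippocampus": 120.0,
            "striatum": 125.0,
            "thalamus": 130.0,
            "cerebellum": 135.0,
        }
    )
    # FDG-like uptake, kBq/mL
    pet_uptake: dict = field(
        default_factory=lambda: {
            "background": 0.0,
            "head": 40.0,
            "parenchyma": 120.0,
            "cortex": 180.0,
            "hippocampus": 170.0,
            "striatum": 190.0,
            "thalamus": 175.0,
            "cerebellum": 150.0,
        }
    )
    bias_amplitude: float = 0.2
    noise_sigma_mr: float = 4.0
    noise_sigma_pet: float = 5.0
    psf_fwhm_mm: float = 0.8
    deform_amplitude_vox: float = 2.5
    deform_smoothness_mm: float = 2.0
    # multiplicative BL -> FU uptake change: up in cortex/hippocampus/thalamus,
    # down in striatum, reference cerebellum stable
    treatment_effect: dict = field(
        default_factory=lambda: {
            "cortex": 1.10,
            "hippocampus": 1.08,
            "striatum": 0.90,
            "thalamus": 1.08,
            "cerebellum": 1.00,
            "parenchyma": 1.00,
            "head": 1.00,
            "background": 1.00,
        }
    )
    injected_dose_kbq: float = 5550.0  # ~0.15 mCi
    injected_dose_sd: float = 300.0
    body_weight_g: float = 25.0
    body_weight_sd: float = 2.0
    seed: int = 0


def cpu_preset(**overrides) -> PhantomSpec:
    """Down-scaled grid (40 x 64 x 64) for CPU-budget experiments.

    In-plane spacing doubles so the field of view is unchanged.
    """
    kw = dict(
        grid_shape=(40, 64, 64),
        spacing_mm=(0.8, 0.3125, 0.3125),
        deform_amplitude_vox=1.8,
    )
    kw.update(overrides)
    return PhantomSpec(**kw)


@dataclass
class SubjectRecord:
    """One scan of one mouse, with full synthetic ground truth."""

    mouse_id: str
    session: str  # BL or FU
    injected_dose_kbq: float
    body_weight_g: float
    mr: ImageVolume
    pet: ImageVolume
    brain_mask_gt: BinaryMask
    ivoi_gt: LabelVolume
    forward_field: DisplacementField


def _tissue_template(spec: PhantomSpec) -> np.ndarray:
    """Paint the 8-code tissue map on the template grid."""
    geom = spec.region_geometry
    shape = spec.grid_shape
    head = geom["head"].inside(shape)
    brain = geom["brain"].inside(shape)
    inner = geom["inner"].inside(shape)
    zz = np.arange(shape[0])[:, None, None]
    yy = np.arange(shape[1])[None, :, None]
    caudal = np.broadcast_to(zz >= geom["z_split_frac"] * shape[0], shape)
    dorsal = np.broadcast_to(yy < geom["y_split_frac"] * shape[1], shape)

    tissue = np.zeros(shape, dtype=np.uint8)
    tissue[head] = HEAD
    tissue[brain] = PARENCHYMA
    masks = {
        "cortex": brain & ~inner & dorsal & ~caudal,
        "hippocampus": geom["hippocampus"].inside(shape),
        "striatum": geom["striatum"].inside(shape),
        "thalamus": geom["thalamus"].inside(shape),
        "cerebellum": brain & caudal,
    }
    # regions must be pairwise disjoint in template space
    names = list(masks)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            if np.any(masks[a] & masks[b]):
                raise PhantomSpecError(f"region geometry overlap: {a} collides with {b}")
        if a != "cerebellum" and not np.all(brain[masks[a]]):
            raise PhantomSpecError(f"region {a} extends outside the brain")
    from .core import REGION_CODES

    for name, m in masks.items():
        tissue[m] = REGION_CODES[name]
    return tissue


def _lut(values: dict) -> np.ndarray:
    lut = np.zeros(8, dtype=np.float64)
    for code, name in _TISSUES.items():
        lut[code] = values[name]
    return lut


def make_template(spec: PhantomSpec) -> tuple[ImageVolume, LabelVolume]:
    """Noiseless MR template and the five-region VOI label template."""
    tissue = _tissue_template(spec)
    mr = _lut(spec.mr_intensity)[tissue].astype(np.float32)
    labels = np.where(tissue <= 5, tissue, 0).astype(np.uint8)
    present = set(np.unique(labels))
    if present != set(range(6)):
        raise PhantomSpecError(f"template must contain codes 0..5, got {sorted(present)}")
    return ImageVolume(mr, spec.spacing_mm), LabelVolume(labels, spec.spacing_mm)


def _sample_forward_field(spec: PhantomSpec, rng: np.random.Generator) -> DisplacementField:
    """Smoothed Gaussian noise, scaled so max |component| = deform_amplitude_vox."""
    shape = spec.grid_shape
    sigma_vox = tuple(spec.deform_smoothness_mm / s for s in spec.spacing_mm)
    vec = np.empty((*shape, 3))
    for c in range(3):
        raw = rng.standard_normal(shape)
        smooth = gaussian_filter(raw, sigma=sigma_vox, mode="nearest")
        peak = np.abs(smooth).max()
        vec[..., c] = smooth / peak * spec.deform_amplitude_vox if peak > 0 else 0.0
    return DisplacementField(vec, spec.spacing_mm, "forward")


def sample_invertible_field(
    spec: PhantomSpec, rng: np.random.Generator, max_tries: int = 5
) -> DisplacementField:
    """Draw a forward field whose grid Jacobian is positive everywhere.

    A draw failing the certificate is resampled with the amplitude reduced by
    20% (logged); five failures raise.
    """
    amp = spec.deform_amplitude_vox
    for attempt in range(max_tries):
        trial = replace(spec, deform_amplitude_vox=amp)
        fld = _sample_forward_field(trial, rng)
        if jacobian_determinant(fld).min() > 0:
            return fld
        amp *= 0.8
        logger.warning(
            "sampled field not invertible (attempt %d); retrying with amplitude %.2f vox",
            attempt + 1,
            amp,
        )
    raise PhantomSpecError(f"could not sample an invertible field in {max_tries} tries")


def _bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Multiplicative low-order bias: 1 + amplitude * random quadratic in [-1, 1]."""
    shape = spec.grid_shape
    coords = [np.linspace(-1.0, 1.0, s) for s in shape]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    basis = [zz, yy, xx, zz * yy, zz * xx, yy * xx, zz**2, yy**2, xx**2]
    w = rng.standard_normal(len(basis))
    f = sum(wi * b for wi, b in zip(w, basis))
    peak = np.abs(f).max()
    if peak > 0:
        f = f / peak
    return 1.0 + spec.bias_amplitude * f


def _psf_sigma_vox(spec: PhantomSpec) -> tuple[float, float, float]:
    sigma_mm = spec.psf_fwhm_mm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    return tuple(sigma_mm / s for s in spec.spacing_mm)


def generate_subject(
    template: tuple[ImageVolume, LabelVolume],
    spec: PhantomSpec,
    mouse_id: str,
    session: str,
    seed: int,
    forward_field: DisplacementField | None = None,
) -> SubjectRecord:
    """Render one scan; pass ``forward_field`` to share anatomy across sessions."""
    if session not in (BL, FU):
        raise ValueError(f"session must be '{BL}' or '{FU}'")
    rng = np.random.default_rng(seed)
    mr_template, _ = template
    tissue_t = _tissue_template(spec)

    if forward_field is None:
        forward_field = sample_invertible_field(spec, rng)
    if np.any(forward_field.vectors):
        inverse = invert_field(forward_field)
        mr_geom = warp_volume(mr_template, inverse, interp="linear").data.astype(np.float64)
        tissue = warp_volume(
            LabelVolume(tissue_t, spec.spacing_mm), inverse, interp="nearest"
        ).data
    else:
        mr_geom = mr_template.data.astype(np.float64)
        tissue = tissue_t

    brain_mask = (tissue >= 1) & (tissue <= PARENCHYMA)
    ivoi = np.where(tissue <= 5, tissue, 0).astype(np.uint8)

    # MR: warped intensities * bias + noise
    mr = mr_geom * _bias_field(spec, rng)
    if spec.noise_sigma_mr > 0:
        mr = mr + rng.normal(0.0, spec.noise_sigma_mr, mr.shape)

    # PET: session-dependent piecewise-constant uptake, warped with
    # label-safe nearest sampling, then PSF blur and counting noise
    uptake_lut = _lut(spec.pet_uptake)
    if session == FU:
        uptake_lut = uptake_lut * _lut(spec.treatment_effect)
    pet = uptake_lut[tissue]
    sigma = _psf_sigma_vox(spec)
    if spec.psf_fwhm_mm > 0:
        pet = gaussian_filter(pet, sigma=sigma, mode="nearest")
    if spec.noise_sigma_pet > 0:
        pet = pet + rng.normal(0.0, spec.noise_sigma_pet, pet.shape)

    injected = max(float(rng.normal(spec.injected_dose_kbq, spec.injected_dose_sd)), 1.0)
    weight = max(float(rng.normal(spec.body_weight_g, spec.body_weight_sd)), 1.0)

    return SubjectRecord(
        mouse_id=mouse_id,
        session=session,
        injected_dose_kbq=injected,
        body_weight_g=weight,
        mr=ImageVolume(mr.astype(np.float32), spec.spacing_mm),
        pet=ImageVolume(pet.astype(np.float32), spec.spacing_mm),
        brain_mask_gt=BinaryMask(brain_mask, spec.spacing_mm),
        ivoi_gt=LabelVolume(ivoi, spec.spacing_mm),
        forward_field=forward_field,
    )


def generate_cohort(spec: PhantomSpec, n_mice: int = 18) -> list[SubjectRecord]:
    """Paired-scan cohort: 2 records per mouse, anatomy shared within a mouse.

    Per-mouse and per-session seeds are derived deterministically from
    ``spec.seed``, so the same spec always regenerates the same cohort.
    """
    if n_mice < 1:
        raise ValueError("n_mice must be >= 1")
    template = make_template(spec)
    records: list[SubjectRecord] = []
    for i in range(n_mice):
        mouse_id = f"m{i + 1:02d}"
        anat_seed = int(np.random.SeedSequence([spec.seed, i, 0]).generate_state(1)[0] % (2**31))
        anat_rng = np.random.default_rng(anat_seed)
        fld = sample_invertible_field(spec, anat_rng)
        for j, session in enumerate((BL, FU)):
            scan_seed = int(
                np.random.SeedSequence([spec.seed, i, j + 1]).generate_state(1)[0] % (2**31)
            )
            records.append(
                generate_subject(template, spec, mouse_id, session, scan_seed, forward_field=fld)
            )
    return records


def write_cohort(
    records: list[SubjectRecord], outdir: str | Path, analyze: bool = False
) -> Path:
    """Write per-subject volumes (NIfTI, or Analyze 7.5) and a manifest CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    ext = ".hdr" if analyze else ".nii.gz"
    rows = []
    for rec in records:
        stem = f"{rec.mouse_id}_{rec.session}"
        paths = {}
        for kind, vol in (
            ("mr", rec.mr),
            ("pet", rec.pet),
            ("brain_mask_gt", rec.brain_mask_gt),
            ("ivoi_gt", rec.ivoi_gt),
        ):
            p = outdir / f"{stem}_{kind}{ext}"
            save_volume(vol, p)
            paths[kind] = p.name
        rows.append(
            {
                "mouse_id": rec.mouse_id,
                "session": rec.session,
                "injected_dose_kbq": rec.injected_dose_kbq,
                "body_weight_g": rec.body_weight_g,
                **paths,
            }
        )
    manifest = outdir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest
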