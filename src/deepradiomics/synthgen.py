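"""Seeded synthetic cohorts: multimodal 3D phantoms with tumour ROIs.

Each phantom subject carries five co-registered volumes (FLAIR, T1, T2, FA,
MD) on a small isotropic grid, an exact ellipsoidal tumour mask, and
demographics drawn from class-dependent distributions that mirror a glioma
cohort: IDH-mutant patients are younger (39.1 +/- 8.7 y) than wildtype
(55.1 +/- 13.5 y), and mutants form the majority (146 of 206).

The class signal is injected where the biology puts it: inside the tumour,
wildtype gliomas get lower mean diffusivity (denser cellularity) and higher
fractional anisotropy than mutants, plus small structural-intensity shifts.
Backgrounds are smoothed Gaussian random fields; this emulates texture, not
MR physics (no k-space, bias fields or partial volume).

FA/MD can be produced analytically (default, fast) or by simulating a
diffusion-weighted series from an axially symmetric tensor field and
fitting it with :mod:`~deepradiomics.dtifit`, which exercises the full
tensor path.
"""

from __future__ import annotations

import csv
import dataclasses
import zlib
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml
from scipy import ndimage
from scipy.stats import truncnorm

from .dtifit import DWISeries, fit_tensor
from .volio import ROIMask, SubjectRecord, Volume, write_mask, write_volume

STRUCTURAL = ("FLAIR", "T1", "T2")

#: tumour-interior mean shifts per modality, per class, in the units of the
#: map (structural maps are arbitrary units with background sd 1).
DEFAULT_CLASS_EFFECTS: dict[str, dict[str, float]] = {
    "FLAIR": {"mutant": 2.0, "wildtype": 2.2},
    "T1": {"mutant": -1.0, "wildtype": -1.2},
    "T2": {"mutant": 1.5, "wildtype": 1.7},
    "FA": {"mutant": -0.08, "wildtype": 0.10},  # background FA 0.30
    "MD": {"mutant": 0.50e-3, "wildtype": 0.12e-3},  # background MD 0.80e-3
}

DEFAULT_BACKGROUND_MEAN = {"FLAIR": 0.0, "T1": 0.0, "T2": 0.0, "FA": 0.30, "MD": 0.80e-3}
DEFAULT_BACKGROUND_SD = {"FLAIR": 1.0, "T1": 1.0, "T2": 1.0, "FA": 0.05, "MD": 0.05e-3}


@dataclasses.dataclass(frozen=True)
class PhantomSpec:
    """Geometry, texture and class-contrast parameters of one phantom."""

    grid_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_mm: float = 1.0
    tumour_center: tuple[float, float, float] = (24.0, 24.0, 24.0)
    tumour_semiaxes: tuple[float, float, float] = (10.0, 8.0, 7.0)
    center_jitter: float = 2.0  # voxels, per-subject uniform jitter
    semiaxis_jitter: float = 1.5
    smoothing_fwhm: float = 4.0  # mm, background texture correlation length
    noise_sd: float = 0.3  # unsmoothed voxel noise, units of background sd
    background_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: DEFAULT_BACKGROUND_MEAN
    )
    background_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: DEFAULT_BACKGROUND_SD
    )
    class_effects: Mapping[str, Mapping[str, float]] = dataclasses.field(
        default_factory=lambda: DEFAULT_CLASS_EFFECTS
    )
    fa_md_route: str = "analytic"  # or "dwi"
    rician_snr: float = np.inf  # SNR of the simulated DWI (inf = noiseless)
    dwi_bval: float = 1000.0
    dwi_n_directions: int = 30

    def __post_init__(self) -> None:
        if any(
            a + j >= s / 2
            for a, j, s in zip(self.tumour_semiaxes,
                               (self.semiaxis_jitter,) * 3, self.grid_shape)
        ):
            raise ValueError("tumour semi-axes (plus jitter) must fit in the grid")
        if self.noise_sd < 0 or self.rician_snr <= 0:
            raise ValueError("noise parameters must be >= 0 / SNR > 0")
        if self.fa_md_route not in ("analytic", "dwi"):
            raise ValueError("fa_md_route must be 'analytic' or 'dwi'")


@dataclasses.dataclass(frozen=True)
class DemographicsSpec:
    """Class-conditional age distributions and cohort composition."""

    age_mean: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"mutant": 39.1, "wildtype": 55.1}
    )
    age_sd: Mapping[str, float] = dataclasses.field(
        default_factory=lambda: {"mutant": 8.7, "wildtype": 13.5}
    )
    age_bounds: tuple[float, float] = (18.0, 90.0)
    mutant_fraction: float = 146 / 206
    female_fraction: float = 100 / 206

    def __post_init__(self) -> None:
        if not 0 < self.mutant_fraction < 1:
            raise ValueError("prevalence must be in (0, 1)")
        if any(sd <= 0 for sd in self.age_sd.values()):
            raise ValueError("age sd must be > 0")


def _subject_rng(seed: int, subject_id: str) -> np.random.Generator:
    """Deterministic per-subject stream: (seed, subject_id) fixes everything."""
    sid_hash = zlib.crc32(subject_id.encode("utf-8"))
    return np.random.default_rng(np.random.SeedSequence([seed, sid_hash]))


def _smooth_field(shape, rng, fwhm_vox: float) -> np.ndarray:
    field = rng.standard_normal(shape)
    sigma = fwhm_vox / 2.355
    sm = ndimage.gaussian_filter(field, sigma)
    sd = sm.std()
    return sm / sd if sd > 0 else sm


def ellipsoid_mask(shape, center, semiaxes) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    d = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semiaxes))
    return d <= 1.0


# ---------------------------------------------------------------------------
# Diffusion signal simulation


def make_gradient_scheme(
    n_directions: int = 30, bval: float = 1000.0, n_b0: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """A deterministic quasi-uniform (Fibonacci-sphere) gradient scheme:
    ``n_b0`` unweighted volumes plus ``n_directions`` at ``bval``."""
    i = np.arange(n_directions)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - (2.0 * i + 1.0) / n_directions
    r = np.sqrt(1.0 - z**2)
    dirs = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])
    bvals = np.r_[np.zeros(n_b0), np.full(n_directions, bval)]
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    return bvals, bvecs


def tensor_from_fa_md(fa: np.ndarray, md: np.ndarray, direction) -> np.ndarray:
    """Axially symmetric (prolate) tensors with prescribed FA and MD.

    With l1 = md (1 + 2a), l2 = l3 = md (1 - a) the anisotropy solves
    a = FA / sqrt(3 - 2 FA^2); the principal axis is ``direction``.
    """
    fa = np.clip(np.asarray(fa, float), 0.0, 0.95)
    md = np.asarray(md, float)
    a = fa / np.sqrt(3.0 - 2.0 * fa**2)
    l1 = md * (1.0 + 2.0 * a)
    l2 = md * (1.0 - a)
    e = np.asarray(direction, float)
    e = e / np.linalg.norm(e)
    outer = np.einsum("i,j->ij", e, e)
    eye = np.eye(3)
    return (
        (l1 - l2)[..., None, None] * outer + l2[..., None, None] * eye
    )


def simulate_dwi(
    tensors: np.ndarray,
    bvals: np.ndarray,
    bvecs: np.ndarray,
    s0: float | np.ndarray = 1000.0,
    rician_snr: float = np.inf,
    seed: int = 0,
) -> DWISeries:
    """Mono-exponential DWI signals S = S0 exp(-b g' D g), optionally with
    Rician noise at the stated SNR (sigma = S0 / SNR)."""
    tensors = np.asarray(tensors, float)
    if tensors.shape[-2:] != (3, 3):
        raise ValueError("tensor field must be (..., 3, 3)")
    bvals = np.asarray(bvals, float).ravel()
    bvecs = np.asarray(bvecs, float)
    if bvecs.shape == (3, bvals.size):
        bvecs = bvecs.T
    # g' D g for every voxel and acquisition
    gdg = np.einsum("ni,...ij,nj->...n", bvecs, tensors, bvecs)
    s0_arr = np.broadcast_to(np.asarray(s0, float), tensors.shape[:-2])
    signals = s0_arr[..., None] * np.exp(-bvals * gdg)
    if np.isfinite(rician_snr):
        rng = np.random.default_rng(seed)
        sigma = float(np.mean(s0_arr)) / rician_snr
        n1 = rng.normal(0.0, sigma, signals.shape)
        n2 = rng.normal(0.0, sigma, signals.shape)
        signals = np.sqrt((signals + n1) ** 2 + n2**2)
    return DWISeries(signals=signals, bvals=bvals, bvecs=bvecs)


# ---------------------------------------------------------------------------
# Subject and cohort generation


def _draw_demographics(
    rng: np.random.Generator, demo: DemographicsSpec, label: str
) -> tuple[float, str]:
    """Age from the label's truncated normal, then sex; drawn first from the
    subject stream so demographics can be replayed without volumes."""
    mu, sd = demo.age_mean[label], demo.age_sd[label]
    lo, hi = demo.age_bounds
    a, b = (lo - mu) / sd, (hi - mu) / sd
    age = float(truncnorm.rvs(a, b, loc=mu, scale=sd, random_state=rng))
    sex = "F" if rng.random() < demo.female_fraction else "M"
    return age, sex


def cohort_demographics(
    n: int, demo: DemographicsSpec | None = None, seed: int = 0
) -> list[dict]:
    """Labels, ages and sexes of a cohort without generating any volumes —
    exactly the demographics :func:`generate_cohort` would produce."""
    demo = demo or DemographicsSpec()
    rows = []
    for i, lab in enumerate(cohort_labels(n, demo.mutant_fraction, seed)):
        sid = f"sub-{i:04d}"
        age, sex = _draw_demographics(_subject_rng(seed, sid), demo, lab)
        rows.append({"subject_id": sid, "label": lab, "age": age, "sex": sex})
    return rows


def generate_subject(
    spec: PhantomSpec,
    demo: DemographicsSpec,
    label: str,
    subject_id: str,
    seed: int = 0,
) -> SubjectRecord:
    """One phantom subject, fully determined by (seed, subject_id)."""
    if label not in ("mutant", "wildtype"):
        raise ValueError(f"label must be 'mutant' or 'wildtype', got {label!r}")
    rng = _subject_rng(seed, subject_id)
    age, sex = _draw_demographics(rng, demo, label)
    shape = spec.grid_shape
    fwhm_vox = spec.smoothing_fwhm / spec.voxel_mm

    center = np.asarray(spec.tumour_center) + rng.uniform(
        -spec.center_jitter, spec.center_jitter, 3
    )
    axes = np.asarray(spec.tumour_semiaxes) + rng.uniform(
        -spec.semiaxis_jitter, spec.semiaxis_jitter, 3
    )
    tumour = ellipsoid_mask(shape, center, axes)

    affine = np.diag([spec.voxel_mm] * 3 + [1.0])
    spacing = (spec.voxel_mm,) * 3
    volumes: dict[str, Volume] = {}

    def textured(mod: str) -> np.ndarray:
        mu, sd = spec.background_mean[mod], spec.background_sd[mod]
        base = mu + sd * _smooth_field(shape, rng, fwhm_vox) if sd > 0 else np.full(shape, mu)
        shift = spec.class_effects.get(mod, {}).get(label, 0.0)
        base = np.where(tumour, base + shift, base)
        if spec.noise_sd > 0 and sd > 0:
            base = base + rng.normal(0, spec.noise_sd * sd, shape)
        return base

    for mod in STRUCTURAL:
        volumes[mod] = Volume(textured(mod), spacing, affine, mod)

    fa_field = np.clip(textured("FA"), 0.0, 0.95)
    md_field = np.clip(textured("MD"), 1e-5, None)
    if spec.fa_md_route == "analytic":
        volumes["FA"] = Volume(fa_field, spacing, affine, "FA")
        volumes["MD"] = Volume(md_field, spacing, affine, "MD")
    else:
        direction = rng.standard_normal(3)
        tensors = tensor_from_fa_md(fa_field, md_field, direction)
        bvals, bvecs = make_gradient_scheme(spec.dwi_n_directions, spec.dwi_bval)
        dwi_seed = int(rng.integers(0, 2**31 - 1))
        dwi = simulate_dwi(tensors, bvals, bvecs, 1000.0, spec.rician_snr, dwi_seed)
        maps = fit_tensor(dwi)
        volumes["FA"] = Volume(maps.fa, spacing, affine, "FA")
        volumes["MD"] = Volume(maps.md, spacing, affine, "MD")

    return SubjectRecord(
        subject_id=subject_id,
        volumes=volumes,
        mask=ROIMask(tumour, spacing, affine),
        age=age,
        sex=sex,
        label=label,
        scanner_id="synthetic",
    )


def cohort_labels(n: int, mutant_fraction: float, seed: int) -> list[str]:
    """Exact class counts by rounding, order shuffled deterministically."""
    n_mut = round(n * mutant_fraction)
    if n_mut < 1 or n - n_mut < 1:
        raise ValueError(f"n={n} leaves a class empty at prevalence {mutant_fraction}")
    labels = ["mutant"] * n_mut + ["wildtype"] * (n - n_mut)
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0xC0F0]))
    rng.shuffle(labels)
    return labels


def generate_cohort(
    n: int,
    spec: PhantomSpec | None = None,
    demo: DemographicsSpec | None = None,
    seed: int = 0,
) -> list[SubjectRecord]:
    """A cohort of n phantom subjects at the configured prevalence."""
    if n < 2:
        raise ValueError("a cohort needs at least 2 subjects")
    spec = spec or PhantomSpec()
    demo = demo or DemographicsSpec()
    labels = cohort_labels(n, demo.mutant_fraction, seed)
    return [
        generate_subject(spec, demo, lab, f"sub-{i:04d}", seed)
        for i, lab in enumerate(labels)
    ]


# ---------------------------------------------------------------------------
# Disk round-trip (the formats the pipeline reads)


def write_cohort(cohort: Sequence[SubjectRecord], out_dir) -> Path:
    """Write a cohort as NIfTI volumes + masks, a demographics CSV and a YAML
    manifest; returns the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for rec in cohort:
        sdir = out / rec.subject_id
        sdir.mkdir(exist_ok=True)
        vol_paths = {}
        for mod, vol in rec.volumes.items():
            p = sdir / f"{mod}.nii.gz"
            write_volume(vol, p)
            vol_paths[mod] = str(p.relative_to(out))
        mask_path = sdir / "mask.nii.gz"
        write_mask(rec.mask, mask_path)
        entries.append(
            {
                "subject_id": rec.subject_id,
                "label": rec.label,
                "age": float(rec.age),
                "sex": rec.sex,
                "scanner_id": rec.scanner_id,
                "volumes": vol_paths,
                "mask": str(mask_path.relative_to(out)),
            }
        )
    with open(out / "demographics.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["subject_id", "age", "sex", "label", "scanner_id"])
        for e in entries:
            w.writerow([e["subject_id"], e["age"], e["sex"], e["label"], e["scanner_id"]])
    manifest = {"subjects": entries}
    mpath = out / "manifest.yaml"
    with open(mpath, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=False)
    return mpath


def load_cohort(manifest_path) -> list[SubjectRecord]:
    """Read a cohort back from a YAML manifest written by :func:`write_cohort`
    (or assembled by hand for real data)."""
    from .volio import read_mask, read_volume

    mpath = Path(manifest_path)
    root = mpath.parent
    with open(mpath) as fh:
        manifest = yaml.safe_load(fh)
    cohort = []
    for e in manifest["subjects"]:
        volumes = {
            mod: read_volume(root / rel, mod) for mod, rel in e["volumes"].items()
        }
        cohort.append(
            SubjectRecord(
                subject_id=e["subject_id"],
                volumes=volumes,
                mask=read_mask(root / e["mask"]),
                age=float(e["age"]),
                sex=e["sex"],
                label=e["label"],
                scanner_id=e.get("scanner_id", "unknown"),
            )
        )
    return cohort
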