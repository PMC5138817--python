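"""Synthetic tumor cohorts with known statistical structure.

Every downstream stage of the pipeline (segmentation, feature extraction,
SVM ranking, survival models) is exercised against phantoms generated here,
so each generator plants a recoverable truth:

* tumor phantoms are ellipsoids of elevated mean intensity whose intratumoral
  texture is a Gaussian random field with a class-specific correlation length
  (the heterogeneity knob);
* class labels (histology or stage surrogates) are coupled to that texture
  parameter;
* survival times follow a proportional-hazards model with a chosen log-hazard
  ratio for a designated high/low feature status, with independent
  exponential right-censoring whose rate is tuned by bisection to hit the
  requested censoring fraction in expectation.

All randomness flows through ``numpy.random.Generator`` (PCG64), so a fixed
seed reproduces a cohort bit-for-bit on any platform.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .io import ImageVolume, ROIMask, write_mask, write_volume

__all__ = [
    "CohortDesign",
    "SyntheticPatient",
    "generate_tumor_phantom",
    "generate_survival",
    "generate_cohort",
    "write_cohort",
]

#: Intensity of the lung background (HU-like) and of the tumor interior.
BACKGROUND_MEAN = -50.0
TUMOR_MEAN = 40.0
#: Additive i.i.d. Gaussian acquisition-noise SD applied everywhere (HU).
NOISE_SD = 10.0
#: SD of the intratumoral heterogeneity field before additive noise (HU).
TEXTURE_SD = 25.0


@dataclass
class CohortDesign:
    """Parameters of the synthetic cohort generator.

    Parameters
    ----------
    n_patients : int
        Cohort size.
    image_shape : tuple of int
        Voxels per axis, (slice, row, column).
    voxel_spacing : tuple of float
        mm per axis.
    tumor_radius_range : tuple of float
        (min, max) equivalent radius in mm; per-patient radii are uniform in
        this range and per-axis semi-axes jitter around it.
    texture_corr_length_by_class : dict
        Label -> Gaussian-field correlation length in mm. Larger values give
        smoother (less heterogeneous) intratumoral texture.
    class_probs : dict
        Label -> probability; must sum to 1.
    beta_feature : float
        Log hazard ratio linking a designated feature's high/low status
        (1 = high) to the event hazard.
    baseline_hazard : float
        Events per month for status-0 patients.
    censor_rate : float
        Expected fraction of censored patients, in [0, 1).
    seed : int
        Master RNG seed.
    """

    n_patients: int = 100
    image_shape: tuple[int, int, int] = (48, 48, 48)
    voxel_spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    tumor_radius_range: tuple[float, float] = (8.0, 12.0)
    texture_corr_length_by_class: dict = field(
        default_factory=lambda: {"A": 1.0, "B": 3.0}
    )
    class_probs: dict = field(default_factory=lambda: {"A": 0.5, "B": 0.5})
    beta_feature: float = 0.0
    baseline_hazard: float = 0.05
    censor_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        self.image_shape = tuple(int(v) for v in self.image_shape)
        self.voxel_spacing = tuple(float(v) for v in self.voxel_spacing)
        if len(self.image_shape) != 3 or len(self.voxel_spacing) != 3:
            raise ValueError("image_shape and voxel_spacing must be 3-vectors")
        if any(s <= 0 for s in self.voxel_spacing):
            raise ValueError("voxel_spacing must be strictly positive")
        lo, hi = self.tumor_radius_range
        if not (0 < lo <= hi):
            raise ValueError("tumor_radius_range must satisfy 0 < min <= max")
        total = sum(self.class_probs.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_probs must sum to 1, got {total}")
        for lbl, cl in self.texture_corr_length_by_class.items():
            if not np.isinf(cl) and cl <= 0:
                raise ValueError(f"correlation length for {lbl!r} must be > 0")
        missing = set(self.class_probs) - set(self.texture_corr_length_by_class)
        if missing:
            raise ValueError(f"no correlation length for classes {sorted(missing)}")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be > 0")
        if not (0 <= self.censor_rate < 1):
            raise ValueError("censor_rate must lie in [0, 1)")

    def to_json(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=2, default=float)

    @classmethod
    def from_json(cls, path: str | os.PathLike) -> "CohortDesign":
        with open(path) as fh:
            d = json.load(fh)
        for key in ("image_shape", "voxel_spacing", "tumor_radius_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass
class SyntheticPatient:
    """One simulated subject: image, ground-truth mask, label, outcome."""

    id: str
    volume: ImageVolume
    mask: ROIMask
    label: str
    os_months: float
    event: int

    def __post_init__(self) -> None:
        if self.mask.n_voxels == 0:
            raise ValueError("mask must be nonempty")
        if self.os_months <= 0:
            raise ValueError("os_months must be > 0")
        if self.event not in (0, 1):
            raise ValueError("event must be 0 or 1")


def _correlated_field(shape, spacing, corr_length_mm, rng) -> np.ndarray:
    """Unit-variance Gaussian random field with given correlation length.

    White noise filtered with a Gaussian kernel of width ``corr_length_mm``
    (in voxel units per axis), then restandardized. corr_length = inf gives
    the degenerate flat-field limit.
    """
    noise = rng.standard_normal(shape)
    if np.isinf(corr_length_mm):
        return np.zeros(shape)
    sigma_vox = [corr_length_mm / s for s in spacing]
    if max(sigma_vox) < 1e-6:
        return noise
    smooth = gaussian_filter(noise, sigma=sigma_vox, mode="wrap")
    sd = smooth.std()
    if sd < 1e-12:  # pathological: kernel wider than the grid
        return np.zeros(shape)
    return smooth / sd


def generate_tumor_phantom(
    design: CohortDesign, label: str, rng: np.random.Generator
) -> tuple[ImageVolume, ROIMask]:
    """Generate one ellipsoidal tumor phantom and its exact ground-truth mask.

    The tumor interior is ``TUMOR_MEAN`` plus a correlated heterogeneity field
    (SD ``TEXTURE_SD``, correlation length set by the label); background is
    ``BACKGROUND_MEAN``. I.i.d. Gaussian noise of SD ``NOISE_SD`` is added
    everywhere.
    """
    shape = design.image_shape
    spacing = np.asarray(design.voxel_spacing)
    extent_mm = np.array(shape) * spacing

    lo, hi = design.tumor_radius_range
    radius = rng.uniform(lo, hi)
    # mild anisotropy so phantoms are not perfect spheres
    semi_axes = radius * rng.uniform(0.85, 1.15, size=3)
    if np.any(2 * semi_axes >= extent_mm):
        raise ValueError(
            f"tumor diameter {2 * semi_axes} mm does not fit in the "
            f"image extent {tuple(extent_mm)} mm"
        )
    center = extent_mm / 2.0

    coords = [np.arange(n) * s for n, s in zip(shape, spacing)]
    zz, yy, xx = np.meshgrid(*coords, indexing="ij")
    dist2 = sum(
        ((g - c) / a) ** 2 for g, c, a in zip((zz, yy, xx), center, semi_axes)
    )
    mask_arr = dist2 <= 1.0

    corr_length = design.texture_corr_length_by_class[label]
    texture = _correlated_field(shape, spacing, corr_length, rng) * TEXTURE_SD

    img = np.full(shape, BACKGROUND_MEAN)
    img[mask_arr] = TUMOR_MEAN + texture[mask_arr]
    img += rng.normal(0.0, NOISE_SD, size=shape)

    vol = ImageVolume(img, tuple(spacing), (0.0, 0.0, 0.0))
    mask = ROIMask(mask_arr, tuple(spacing), (0.0, 0.0, 0.0))
    return vol, mask


def _censor_rate_for(design: CohortDesign, status: np.ndarray) -> float:
    """Exponential censoring rate hitting ``censor_rate`` in expectation.

    With exponential event times (rate h_i = h0*exp(beta*s_i)) and independent
    exponential censoring at rate c, P(censored | i) = c / (c + h_i); the
    cohort-average is monotone in c, so the target is bracketed and solved by
    bisection (Brent).
    """
    if design.censor_rate == 0:
        return 0.0
    hazards = design.baseline_hazard * np.exp(design.beta_feature * status)

    def expected_censored(c: float) -> float:
        return float(np.mean(c / (c + hazards)))

    target = design.censor_rate
    hi = hazards.max()
    # bracket: rate in (0, big]; expected_censored(0+)=0, ->1 as c->inf
    upper = hi * target / (1 - target) * 10 + 1.0
    while expected_censored(upper) < target:
        upper *= 10
    return brentq(lambda c: expected_censored(c) - target, 1e-12, upper)


def generate_survival(
    design: CohortDesign, feature_status: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Draw (os_months, event) under a proportional-hazards model.

    Event times are exponential with hazard h0 * exp(beta_feature * status);
    censoring is independent exponential with rate tuned so the expected
    censored fraction equals ``design.censor_rate``.
    """
    status = np.asarray(feature_status, dtype=float)
    if not np.all(np.isin(status, (0.0, 1.0))):
        raise ValueError("feature_status must be binary 0/1")
    hazards = design.baseline_hazard * np.exp(design.beta_feature * status)
    event_times = rng.exponential(1.0 / hazards)
    c_rate = _censor_rate_for(design, status)
    if c_rate == 0.0:
        censor_times = np.full(status.shape, np.inf)
    else:
        censor_times = rng.exponential(1.0 / c_rate, size=status.shape)
    os_months = np.minimum(event_times, censor_times)
    event = (event_times <= censor_times).astype(int)
    # guard against zero-duration records (measure-zero but finite precision)
    os_months = np.maximum(os_months, 1e-9)
    return os_months, event


def generate_cohort(
    design: CohortDesign,
) -> tuple[list[SyntheticPatient], pd.DataFrame]:
    """Generate a full cohort: phantoms, labels, covariates and outcomes.

    The designated survival feature status is the indicator of the class with
    the LONGEST correlation length (smooth-texture class = high status), so a
    texture feature extracted downstream is statistically linked to survival
    whenever ``beta_feature != 0``.

    Clinical covariates (age, sex, smoking) are drawn independently of the
    image so multivariate adjustment can be exercised without confounding.

    Returns the patient list and a clinical table with columns:
    id, label, age, sex, smoking, os_months, event, status_true.
    """
    rng = np.random.Generator(np.random.PCG64(design.seed))
    labels_all = sorted(design.class_probs)
    probs = np.array([design.class_probs[k] for k in labels_all])
    labels = rng.choice(labels_all, size=design.n_patients, p=probs)

    active = [l for l in labels_all if design.class_probs[l] > 0]
    if len(active) > 1:
        counts = pd.Series(labels).value_counts()
        for lbl in active:
            if counts.get(lbl, 0) < 2:
                raise ValueError(
                    f"fewer than 2 patients drawn for class {lbl!r} "
                    f"(n_patients={design.n_patients}); increase n_patients"
                )

    # high status = class with the longest correlation length among active ones
    high_label = max(
        active, key=lambda l: design.texture_corr_length_by_class[l]
    )
    status = (labels == high_label).astype(int) if len(active) > 1 else np.zeros(
        design.n_patients, dtype=int
    )

    os_months, event = generate_survival(design, status, rng)

    age = rng.normal(60.0, 11.0, size=design.n_patients).round(1)
    sex = rng.choice(["M", "F"], size=design.n_patients, p=[0.65, 0.35])
    smoking = rng.integers(0, 2, size=design.n_patients)

    patients: list[SyntheticPatient] = []
    rows = []
    for i in range(design.n_patients):
        pid = f"P{i:04d}"
        vol, mask = generate_tumor_phantom(design, labels[i], rng)
        patients.append(
            SyntheticPatient(pid, vol, mask, str(labels[i]),
                             float(os_months[i]), int(event[i]))
        )
        rows.append(
            dict(id=pid, label=str(labels[i]), age=float(age[i]),
                 sex=str(sex[i]), smoking=int(smoking[i]),
                 os_months=float(os_months[i]), event=int(event[i]),
                 status_true=int(status[i]))
        )
    clinical = pd.DataFrame(rows).set_index("id")
    return patients, clinical


def write_cohort(
    patients: list[SyntheticPatient],
    clinical: pd.DataFrame,
    design: CohortDesign,
    out_dir: str | os.PathLike,
    mask_format: str = "nii.gz",
) -> None:
    """Write volumes/masks (NIfTI; masks optionally NRRD), clinical CSV, design JSON."""
    out_dir = os.fspath(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    for p in patients:
        write_volume(p.volume, os.path.join(out_dir, f"{p.id}_image.nii.gz"))
        write_mask(p.mask, os.path.join(out_dir, f"{p.id}_mask.{mask_format}"))
    clinical.to_csv(os.path.join(out_dir, "clinical.csv"))
    design.to_json(os.path.join(out_dir, "design.json"))
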