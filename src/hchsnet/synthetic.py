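"""Synthetic lesion images and metadata for end-to-end verification.

The generator produces abstract stand-ins for the six diagnostic
classes — not clinically realistic lesions. Each class recipe controls
the visual channels the feature extractors are built to measure:

* a base hue/saturation/value range (color histograms),
* a spatial-noise amplitude and correlation length (Haralick texture),
* blob eccentricity and radial-harmonic border perturbation (Hu shape),
* metadata priors: age and diameter distributions, symptom
  probabilities (clinical-metadata block).

A single ``separability`` knob in (0, 1] interpolates the class
parameter ranges between fully disjoint (1.0) and heavily overlapping
(near 0), so recovery of the class signal by the full pipeline can be
probed as a function of signal strength. Image and metadata
separability can be set independently, which supports testing that
informative metadata rescues ambiguous images.

Every image is drawn on a skin-toned background as one elliptical blob
with a perturbed border and additive spatially-correlated noise;
patients own one to three lesions so patient-level splitting is
exercised. All artifacts regenerate bit-identically from the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb

from .metadata import BINARY_FIELDS

CLASS_LABELS = ["ACK", "BCC", "MEL", "NEV", "SCC", "SEK"]


@dataclass
class ClassRecipe:
    """Generative parameters for one synthetic class."""

    label: str
    hue_range: list[float]            # degrees
    sat_range: list[float]
    val_range: list[float]
    noise_amp: float                  # intensity units added inside the blob
    noise_corr_len: float             # px, Gaussian correlation length
    eccentricity_range: list[float]   # 0 = circle
    border_irregularity: float        # total radial-harmonic amplitude
    age_mean: float
    age_sd: float
    diameter_mean: float
    diameter_sd: float
    symptom_probs: dict[str, float] = field(default_factory=dict)

    def __post_init__(self):
        for lo, hi in (self.hue_range, self.sat_range, self.val_range,
                       self.eccentricity_range):
            if hi < lo:
                raise ValueError(f"range ({lo}, {hi}) not ordered")
        for p in self.symptom_probs.values():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"symptom probability {p} outside [0, 1]")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ClassRecipe":
        return cls(**d)


def default_recipes(separability: float = 1.0) -> list[ClassRecipe]:
    """Six recipes whose parameter ranges are disjoint at separability
    1.0 and overlap increasingly as it decreases toward 0."""
    if not 0.0 < separability <= 1.0:
        raise ValueError(f"separability must be in (0, 1], got {separability}")
    s = separability
    recipes = []
    hue_centers = np.arange(6) * 60.0 + 30.0
    hue_half = 25.0 + 60.0 * (1.0 - s)
    amp_centers = np.linspace(4.0, 50.0, 6)
    corr_centers = np.linspace(1.0, 6.0, 6)
    ecc_centers = np.linspace(0.05, 0.75, 6)
    irr_centers = np.linspace(0.0, 0.30, 6)
    age_centers = np.linspace(35.0, 75.0, 6)
    diam_centers = np.linspace(4.0, 16.0, 6)

    def pull(center, overall_mean):
        # shrink class centers toward the common mean as s drops
        return overall_mean + (center - overall_mean) * s

    for k, label in enumerate(CLASS_LABELS):
        # 3-bit class code drives which symptoms are prevalent
        code = [(k + 1) >> b & 1 for b in range(3)]
        probs = {}
        for j, name in enumerate(BINARY_FIELDS):
            bit = code[j % 3] if j % 2 == 0 else 1 - code[j % 3]
            probs[name] = float(np.clip(0.5 + (0.45 if bit else -0.45) * s, 0.0, 1.0))
        recipes.append(
            ClassRecipe(
                label=label,
                # lo may be negative at low separability; hue wraps mod 360
                # at draw time
                hue_range=[float(hue_centers[k] - hue_half),
                           float(hue_centers[k] + hue_half)],
                sat_range=[0.45, 0.9],
                val_range=[0.35, 0.75],
                noise_amp=float(pull(amp_centers[k], amp_centers.mean())),
                noise_corr_len=float(pull(corr_centers[k], corr_centers.mean())),
                eccentricity_range=[
                    float(max(0.0, pull(ecc_centers[k], ecc_centers.mean()) - 0.05)),
                    float(min(0.95, pull(ecc_centers[k], ecc_centers.mean()) + 0.05)),
                ],
                border_irregularity=float(max(0.0, pull(irr_centers[k], irr_centers.mean()))),
                age_mean=float(pull(age_centers[k], age_centers.mean())),
                age_sd=6.0,
                diameter_mean=float(pull(diam_centers[k], diam_centers.mean())),
                diameter_sd=1.5,
                symptom_probs=probs,
            )
        )
    return recipes


_SKIN_RGB = np.array([214.0, 172.0, 148.0])


def gen_image(recipe: ClassRecipe, rng: np.random.Generator, size: int = 256) -> np.ndarray:
    """One synthetic lesion photograph as a size x size x 3 uint8 array."""
    bg = _SKIN_RGB + rng.normal(0.0, 4.0, size=3)
    img = np.ones((size, size, 3)) * bg[None, None, :]
    img += rng.normal(0.0, 2.0, size=img.shape)  # sensor noise floor

    # blob geometry
    cy = size / 2 + rng.uniform(-0.08, 0.08) * size
    cx = size / 2 + rng.uniform(-0.08, 0.08) * size
    r0 = rng.uniform(0.22, 0.30) * size
    ecc = rng.uniform(*recipe.eccentricity_range)
    b_axis = r0 * np.sqrt(1.0 - ecc**2)
    angle = rng.uniform(0.0, np.pi)

    ys, xs = np.mgrid[0:size, 0:size]
    dx = xs - cx
    dy = ys - cy
    ca, sa = np.cos(angle), np.sin(angle)
    u = dx * ca + dy * sa
    v = -dx * sa + dy * ca
    rho = np.sqrt((u / r0) ** 2 + (v / b_axis) ** 2)
    phi = np.arctan2(v, u)
    # radial-harmonic border perturbation
    boundary = np.ones_like(phi)
    if recipe.border_irregularity > 0:
        amps = rng.dirichlet(np.ones(3)) * recipe.border_irregularity
        for m, a in zip((2, 3, 5), amps):
            boundary += a * np.cos(m * phi + rng.uniform(0, 2 * np.pi))
    mask = (rho <= boundary).astype(float)
    alpha = gaussian_filter(mask, sigma=1.5)

    # class fill color
    hue = rng.uniform(*recipe.hue_range) % 360.0
    sat = rng.uniform(*recipe.sat_range)
    val = rng.uniform(*recipe.val_range)
    fill = hsv2rgb(np.array([[[hue / 360.0, sat, val]]]))[0, 0] * 255.0

    lesion = np.ones_like(img) * fill[None, None, :]
    if recipe.noise_amp > 0:
        noise = gaussian_filter(
            rng.standard_normal((size, size)), sigma=max(recipe.noise_corr_len, 1e-6)
        )
        sd = noise.std()
        if sd > 0:
            noise = noise / sd * recipe.noise_amp
        lesion += noise[..., None]
    img = img * (1.0 - alpha[..., None]) + lesion * alpha[..., None]
    return np.clip(np.rint(img), 0, 255).astype(np.uint8)


@dataclass
class SyntheticDataset:
    """Images plus a schema-compliant manifest, regenerable from seed."""

    manifest: pd.DataFrame
    images: dict[str, np.ndarray]
    seed: int
    recipes: list[ClassRecipe]


def gen_dataset(
    n_per_class: int,
    separability: float = 1.0,
    seed: int = 0,
    out_dir: str | Path | None = None,
    missingness: float = 0.0,
    metadata_separability: float | None = None,
    size: int = 256,
    recipes: list[ClassRecipe] | None = None,
) -> SyntheticDataset:
    """Generate 6 * n_per_class lesions with metadata.

    ``metadata_separability`` (default: same as ``separability``) draws
    the clinical records from recipes at a different signal level than
    the images — ambiguous images with informative metadata probe the
    value of the metadata block.
    """
    if n_per_class < 1:
        raise ValueError("n_per_class must be >= 1")
    img_recipes = recipes or default_recipes(separability)
    meta_sep = separability if metadata_separability is None else metadata_separability
    meta_recipes = recipes or default_recipes(meta_sep)

    rows = []
    images: dict[str, np.ndarray] = {}
    for k, (rec, mrec) in enumerate(zip(img_recipes, meta_recipes)):
        pat_rng = np.random.default_rng(np.random.SeedSequence([seed, 1000 + k]))
        # assign patients owning 1-3 lesions each
        patient_sizes = []
        remaining = n_per_class
        while remaining > 0:
            take = int(min(pat_rng.integers(1, 4), remaining))
            patient_sizes.append(take)
            remaining -= take
        i = 0
        for p, n_les in enumerate(patient_sizes):
            patient_id = f"PAT_{rec.label}_{p:04d}"
            # patient-level covariates shared by the patient's lesions
            meta_rng = np.random.default_rng(np.random.SeedSequence([seed, 2000 + k, p]))
            age = max(0.0, meta_rng.normal(mrec.age_mean, mrec.age_sd))
            gender = "MALE" if meta_rng.random() < 0.5 else "FEMALE"
            smoke = bool(meta_rng.random() < mrec.symptom_probs["smoke"])
            drink = bool(meta_rng.random() < mrec.symptom_probs["drink"])
            for _ in range(n_les):
                image_id = f"IMG_{rec.label}_{i:05d}"
                img_rng = np.random.default_rng(np.random.SeedSequence([seed, k, i]))
                images[image_id] = gen_image(rec, img_rng, size=size)
                row = {
                    "image_id": image_id,
                    "patient_id": patient_id,
                    "label": rec.label,
                    "age": round(age, 1),
                    "gender": gender,
                    "diameter_1": round(max(0.5, meta_rng.normal(mrec.diameter_mean, mrec.diameter_sd)), 2),
                    "diameter_2": round(max(0.5, meta_rng.normal(mrec.diameter_mean * 0.8, mrec.diameter_sd)), 2),
                    "smoke": smoke,
                    "drink": drink,
                }
                for name in BINARY_FIELDS[2:]:
                    row[name] = bool(meta_rng.random() < mrec.symptom_probs[name])
                rows.append(row)
                i += 1
    manifest = pd.DataFrame(rows)
    if missingness > 0:
        miss_rng = np.random.default_rng(np.random.SeedSequence([seed, 9999]))
        maskable = ["age", "gender", "diameter_1", "diameter_2"] + BINARY_FIELDS
        for col in maskable:
            hit = miss_rng.random(len(manifest)) < missingness
            manifest[col] = manifest[col].astype(object)
            manifest.loc[hit, col] = np.nan

    if out_dir is not None:
        from .preprocess import write_image

        out_dir = Path(out_dir)
        img_dir = out_dir / "images"
        img_dir.mkdir(parents=True, exist_ok=True)
        for image_id, arr in images.items():
            write_image(img_dir / f"{image_id}.png", arr)
        manifest.to_csv(out_dir / "metadata.csv", index=False)

    return SyntheticDataset(
        manifest=manifest, images=images, seed=seed, recipes=list(img_recipes)
    )
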