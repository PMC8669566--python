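"""Synthetic cohorts with a known planted transport-domain effect.

Real structural-MRI cohorts for this kind of analysis are rarely shareable,
so every downstream stage is exercised on phantoms: smooth, strictly
positive tissue-density volumes of unit mass on a common grid, whose shape
shifts linearly with a planted covariate plus independent smooth anatomical
noise.  Ground truth (the planted displacement field per covariate unit and
each subject's effect magnitude) is recorded, which turns direction
recovery, slope calibration and regional localization into checkable
oracles.

Geometry: a three-compartment "head" — an annular high-density shell
(cortex analogue), an interior core (deep tissue), and a low-density central
cavity (ventricle analogue).  The planted effect is the gradient of a radial
potential centred on the shell, i.e. a ring expansion/contraction: the
phantom's version of cortical thinning with ventricular enlargement.
Planting *gradient* (curl-free) fields is deliberate: the optimal-transport
map between a density and its small gradient-field warp linearizes to that
same field, so the embedded truth is exactly what an ideal solver should
recover.

Covariates mimic the study population: age uniform on 58-81 years, peak
oxygen uptake (VO2 peak) on 12.9-34.7 ml/kg/min with a mild negative age
correlation, gender with a 60:112 ratio and an ordinal education level
drawn from the published category frequencies.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage, stats as sstats

from ._fields import identity_grid, jacobian, det3, smooth_field
from .prep import TissueImage, normalize_mass, write_image, read_image
from .transport import warp_density

__all__ = [
    "PhantomSpec",
    "PhantomCohort",
    "AtlasVolume",
    "generate_template",
    "template_compartments",
    "generate_covariates",
    "generate_cohort",
    "generate_atlas",
    "save_cohort",
]

#: male:female ratio of the emulated cohort
GENDER_RATIO = (60, 112)

#: published education-level frequencies for levels 1..8 (percent)
EDUCATION_PCT = {1: 0.0, 2: 0.6, 3: 0.6, 4: 18.6, 5: 28.5, 6: 19.2, 7: 22.1, 8: 10.5}


@dataclass
class PhantomSpec:
    """Parameters of a synthetic cohort.

    ``effect_amplitude`` is the peak displacement (voxels) of a subject at
    the extreme of the covariate range relative to the cohort mean;
    ``noise_amplitude`` is the peak of each subject's independent smooth
    deformation (voxels).  ``vo2_effect_amplitude`` optionally plants a
    second effect driven by VO2 peak whose field has weighted-inner-product
    cosine ``effect_overlap`` with the age effect field.
    """

    n_subjects: int = 40
    grid_shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_mm: float = 2.0
    effect_amplitude: float = 1.0
    noise_amplitude: float = 1.0
    smoothness_mm: float = 6.0
    seed: int = 0
    age_range: tuple[float, float] = (58.0, 81.0)
    vo2_range: tuple[float, float] = (12.9, 34.7)
    age_vo2_corr: float = -0.3
    vo2_effect_amplitude: float = 0.0
    effect_overlap: float = 0.7

    def __post_init__(self):
        self.grid_shape = tuple(int(n) for n in self.grid_shape)
        if len(self.grid_shape) != 3:
            raise ValueError("grid_shape must have three axes")
        if min(self.grid_shape) < 16:
            raise ValueError(
                f"grid {self.grid_shape} too small to contain the three "
                "phantom compartments; need >= 16 voxels per axis"
            )
        if self.voxel_size_mm <= 0 or self.smoothness_mm <= 0:
            raise ValueError("voxel_size_mm and smoothness_mm must be positive")
        if self.effect_amplitude < 0 or self.noise_amplitude < 0:
            raise ValueError("amplitudes must be nonnegative")
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be positive")
        if abs(self.age_vo2_corr) > 0.99:
            raise ValueError("target age-vo2 correlation must be within +/-0.99")


@dataclass
class AtlasVolume:
    """Integer-labelled parcellation of the reference grid (0 = background)."""

    labels: np.ndarray
    region_table: pd.DataFrame  # columns: label, name

    @property
    def region_labels(self) -> np.ndarray:
        return self.region_table["label"].to_numpy()

    @property
    def n_regions(self) -> int:
        return len(self.region_table)


@dataclass
class PhantomCohort:
    """A generated cohort with its ground truth."""

    spec: PhantomSpec
    template: TissueImage
    images: list[TissueImage]
    covariates: pd.DataFrame
    truth_direction: dict[str, np.ndarray]  # displacement per covariate unit
    truth_scores: dict[str, np.ndarray]  # centered covariate values
    displacements: list[np.ndarray] = field(default_factory=list)
    atlas: AtlasVolume | None = None


def template_compartments(spec: PhantomSpec) -> dict[str, np.ndarray]:
    """Boolean masks of the shell / core / cavity used to build the template."""
    g = identity_grid(spec.grid_shape)
    c = (np.array(spec.grid_shape) - 1) / 2.0
    r = np.sqrt(np.sum((g - c) ** 2, axis=-1))
    R = 0.38 * min(spec.grid_shape)
    return {
        "cavity": r < 0.35 * R,
        "core": (r >= 0.35 * R) & (r < 0.8 * R),
        "shell": (r >= 0.8 * R) & (r <= R),
    }


def generate_template(spec: PhantomSpec) -> TissueImage:
    """Three-compartment radial template: shell, core, central cavity.

    Densities 1.0 / 0.5 / 0.05 before Gaussian smoothing (sigma 1.5 voxels),
    epsilon-floored and normalized to unit mass.
    """
    masks = template_compartments(spec)
    raw = (
        1.0 * masks["shell"].astype(float)
        + 0.5 * masks["core"]
        + 0.05 * masks["cavity"]
    )
    raw = ndimage.gaussian_filter(raw, 1.5, mode="reflect")
    img = TissueImage(
        data=raw,
        voxel_size_mm=(spec.voxel_size_mm,) * 3,
        tissue_class="phantom",
        subject_id="template",
    )
    return normalize_mass(img)


def generate_covariates(spec: PhantomSpec) -> pd.DataFrame:
    """Cohort covariate table with the study's ranges and correlations.

    Age and VO2 peak are drawn through a Gaussian copula so their Pearson
    correlation matches the target (the latent correlation is pre-warped by
    the sin transform that relates normal and uniform-score correlations),
    then mapped monotonically onto the published min/max ranges.
    """
    if spec.n_subjects < 4:
        raise ValueError("need at least 4 subjects for covariate generation")
    rng = np.random.default_rng(spec.seed)
    n = spec.n_subjects
    # corr of uniforms under a Gaussian copula: (6/pi) asin(rho/2)
    rho = 2.0 * np.sin(np.pi * spec.age_vo2_corr / 6.0)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n)
    u = sstats.norm.cdf(z)
    age = spec.age_range[0] + (spec.age_range[1] - spec.age_range[0]) * u[:, 0]
    vo2 = spec.vo2_range[0] + (spec.vo2_range[1] - spec.vo2_range[0]) * u[:, 1]
    p_male = GENDER_RATIO[0] / sum(GENDER_RATIO)
    gender = (rng.random(n) < p_male).astype(int)
    levels = np.array(sorted(EDUCATION_PCT))
    probs = np.array([EDUCATION_PCT[k] for k in levels], dtype=float)
    probs /= probs.sum()
    education = rng.choice(levels, size=n, p=probs)
    return pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(n)],
            "age": age,
            "vo2_peak": vo2,
            "gender": gender,
            "education": education,
        }
    )


def _radial_potential_field(spec: PhantomSpec, center_frac: float, width_frac: float) -> np.ndarray:
    """Unit-peak gradient field of a radial Gaussian-bump potential."""
    g = identity_grid(spec.grid_shape)
    c = (np.array(spec.grid_shape) - 1) / 2.0
    r = np.sqrt(np.sum((g - c) ** 2, axis=-1))
    R = 0.38 * min(spec.grid_shape)
    phi = np.exp(-((r - center_frac * R) ** 2) / (2.0 * (width_frac * R) ** 2))
    E = np.stack(np.gradient(phi), axis=-1)
    peak = np.sqrt(np.sum(E**2, axis=-1)).max()
    return E / peak


def effect_fields(spec: PhantomSpec, template: TissueImage) -> dict[str, np.ndarray]:
    """Unit-peak planted effect fields (gradients of radial potentials).

    The age field is a ring expansion centred on the shell.  When a VO2
    effect is requested, a second gradient field is mixed with the first so
    that their cosine in the sqrt(I0)-weighted embedding equals
    ``effect_overlap`` (linear combinations of gradient fields stay
    gradient fields).
    """
    E_age = _radial_potential_field(spec, center_frac=0.85, width_frac=0.25)
    fields = {"age": E_age}
    if spec.vo2_effect_amplitude != 0.0:
        E_b = _radial_potential_field(spec, center_frac=0.45, width_frac=0.30)
        w = np.sqrt(template.data)[..., None]

        def dot(a, b):
            return float(np.sum(a * b * w * w))

        e1 = E_age / np.sqrt(dot(E_age, E_age))
        b_perp = E_b - dot(E_b, e1) * e1
        e2 = b_perp / np.sqrt(dot(b_perp, b_perp))
        mix = spec.effect_overlap * e1 + np.sqrt(1.0 - spec.effect_overlap**2) * e2
        peak = np.sqrt(np.sum(mix**2, axis=-1)).max()
        fields["vo2_peak"] = mix / peak
    return fields


def generate_cohort(spec: PhantomSpec) -> PhantomCohort:
    """Generate a full phantom cohort with recorded ground truth.

    Subject ``i``'s image is the template pushed forward by the displacement

        d_i = s_i^age * A_age * E_age + s_i^vo2 * A_vo2 * E_vo2 + noise_i,

    where ``s_i = (c_i - mean(c)) / (range(c)/2)`` is the centered covariate
    on a [-1, 1]-ish scale, ``A`` the planted amplitudes (voxels) and
    ``noise_i`` an independent smooth random field.  The warp is applied
    mass-preservingly (change of variables, not intensity interpolation) and
    the result re-normalized to unit mass.
    """
    rng = np.random.default_rng(spec.seed)
    template = generate_template(spec)
    cov = generate_covariates(spec)
    fields = effect_fields(spec, template)

    half_ranges = {
        "age": (spec.age_range[1] - spec.age_range[0]) / 2.0,
        "vo2_peak": (spec.vo2_range[1] - spec.vo2_range[0]) / 2.0,
    }
    amplitudes = {"age": spec.effect_amplitude, "vo2_peak": spec.vo2_effect_amplitude}

    truth_direction = {}
    truth_scores = {}
    for name, E in fields.items():
        # displacement per covariate unit
        truth_direction[name] = E * (amplitudes[name] / half_ranges[name])
        truth_scores[name] = (
            cov[name].to_numpy() - cov[name].to_numpy().mean()
        )

    sigma_vox = spec.smoothness_mm / spec.voxel_size_mm
    images = []
    displacements = []
    for i in range(spec.n_subjects):
        d = np.zeros(spec.grid_shape + (3,))
        for name in fields:
            d = d + truth_scores[name][i] * truth_direction[name]
        if spec.noise_amplitude > 0:
            noise = rng.standard_normal(spec.grid_shape + (3,))
            noise = smooth_field(noise, sigma_vox)
            peak = np.sqrt(np.sum(noise**2, axis=-1)).max()
            d = d + noise * (spec.noise_amplitude / peak)
        jd = det3(jacobian(identity_grid(spec.grid_shape) + d))
        if jd.min() <= 0:
            raise ValueError(
                f"planted warp folds for subject {i} (min Jacobian "
                f"{jd.min():.3g}); reduce effect or noise amplitude"
            )
        img = warp_density(d, template)
        img = normalize_mass(img)
        img.subject_id = cov["subject_id"].iloc[i]
        images.append(img)
        displacements.append(d)

    return PhantomCohort(
        spec=spec,
        template=template,
        images=images,
        covariates=cov,
        truth_direction=truth_direction,
        truth_scores=truth_scores,
        displacements=displacements,
    )


def generate_atlas(
    spec: PhantomSpec, n_regions: int, template: TissueImage | None = None
) -> AtlasVolume:
    """Partition the template support into ``n_regions`` contiguous regions.

    Seeded k-means on the voxel coordinates of the support produces a
    Voronoi-like parcellation with every region nonempty; label 0 is
    background.
    """
    from sklearn.cluster import KMeans

    if n_regions < 2:
        raise ValueError("need at least 2 regions")
    if template is None:
        template = generate_template(spec)
    support = template.data > 0.1 * template.data.mean()
    coords = np.argwhere(support).astype(float)
    if n_regions > len(coords):
        raise ValueError(
            f"n_regions={n_regions} exceeds the {len(coords)} support voxels"
        )
    km = KMeans(n_clusters=n_regions, n_init=1, random_state=spec.seed)
    assignments = km.fit_predict(coords)
    labels = np.zeros(spec.grid_shape, dtype=np.int32)
    labels[tuple(coords.astype(int).T)] = assignments + 1
    table = pd.DataFrame(
        {
            "label": np.arange(1, n_regions + 1),
            "name": [f"region_{k:02d}" for k in range(1, n_regions + 1)],
        }
    )
    return AtlasVolume(labels=labels, region_table=table)


def save_cohort(cohort: PhantomCohort, out_dir) -> None:
    """Write a cohort to disk: NIfTI volumes, covariate CSV, JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_image(cohort.template, out / "template.nii.gz")
    for img in cohort.images:
        write_image(img, out / f"{img.subject_id}.nii.gz")
    cohort.covariates.to_csv(out / "covariates.csv", index=False)
    if cohort.atlas is not None:
        import nibabel as nib

        affine = np.diag([cohort.spec.voxel_size_mm] * 3 + [1.0])
        nib.save(
            nib.Nifti1Image(cohort.atlas.labels.astype(np.int16), affine),
            out / "atlas.nii.gz",
        )
        cohort.atlas.region_table.to_csv(out / "atlas_labels.csv", index=False)
    sidecar = {
        "spec": asdict(cohort.spec),
        "truth_scores": {k: v.tolist() for k, v in cohort.truth_scores.items()},
    }
    (out / "phantom.json").write_text(json.dumps(sidecar, indent=2, sort_keys=True))


def load_cohort_images(cohort_dir) -> tuple[TissueImage, list[TissueImage], pd.DataFrame]:
    """Read back the template, subject images and covariates of a saved cohort."""
    d = Path(cohort_dir)
    cov = pd.read_csv(d / "covariates.csv")
    template = read_image(d / "template.nii.gz", subject_id="template")
    images = [
        read_image(d / f"{sid}.nii.gz", subject_id=sid) for sid in cov["subject_id"]
    ]
    return template, images, cov
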