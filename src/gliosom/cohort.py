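"""Synthetic multiparametric glioma cohort generator.

Builds reproducible cohorts of six-channel brain volumes (CE-T1WI, T2WI,
FLAIR, ADC, rCBV, FDOPA-SUV) with the statistical structure the clustering
pipeline assumes: a spherical brain, a spherical tumor (FLAIR-hyperintense
ROI), and connected hypermetabolic / high-perfusion foci inside the tumor
whose expected volume fractions differ by IDH genotype — wild-type tumors
carry larger high-FDOPA and high-rCBV sub-volumes, and wild-type patients
are older on average.  T2WI and ADC share a latent noise field so the two
channels are positively correlated inside the brain.

Geometry is deliberately minimal (spheres and grown blobs): enough to
exercise 3-D masking, stride sampling, and class-conditional label
fractions without pretending anatomical realism.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field, replace
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .preprocess import CHANNEL_NAMES, N_CHANNELS, MultiparametricStudy

GENOTYPES = ("wildtype", "mutant")

#: Compartment ids in the ground-truth map.
BACKGROUND, NORMAL_BRAIN, TUMOR_BULK, HYPERMETABOLIC_FOCUS, PERFUSION_FOCUS = range(5)

COMPARTMENT_NAMES = {
    NORMAL_BRAIN: "normal_brain",
    TUMOR_BULK: "tumor_bulk",
    HYPERMETABOLIC_FOCUS: "hypermetabolic_focus",
    PERFUSION_FOCUS: "perfusion_focus",
}

# Channel means per compartment, arbitrary intensity units, channel order
# cet1, t2, flair, adc, rcbv, fdopa.  Tumor bulk is T2/FLAIR/ADC-bright,
# the hypermetabolic focus is FDOPA-bright, the perfusion focus rCBV-bright.
_DEFAULT_COMPARTMENT_MEANS: dict[str, tuple[float, ...]] = {
    "normal_brain": (1.0, 1.0, 1.0, 1.0, 1.0, 1.0),
    "tumor_bulk": (1.2, 1.8, 2.0, 1.6, 1.1, 1.2),
    "hypermetabolic_focus": (1.4, 1.6, 1.8, 1.2, 1.3, 2.5),
    "perfusion_focus": (1.6, 1.5, 1.7, 1.1, 2.4, 1.4),
}


@dataclass
class CohortSpec:
    """Parameters of a synthetic cohort.

    Defaults mirror the reference study conditions: 62 subjects with a
    33:29 wild-type:mutant split, older wild-type patients, and larger
    hypermetabolic/perfusion focus fractions in wild-type tumors.
    ``focus_fraction_by_class[genotype]`` is ``(hypermetabolic, perfusion)``
    as expected fractions of tumor voxels.
    """

    n_subjects: int = 62
    class_balance: float = 33 / 62  # fraction of wild-type subjects
    volume_shape: tuple[int, int, int] = (48, 48, 48)
    compartment_means: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: dict(_DEFAULT_COMPARTMENT_MEANS)
    )
    focus_fraction_by_class: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"wildtype": (0.25, 0.15), "mutant": (0.05, 0.05)}
    )
    noise_sd: float | tuple[float, ...] = 0.15
    t2_adc_rho: float = 0.7  # shared fraction of the T2/ADC noise variance
    age_params: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"wildtype": (58.0, 12.0), "mutant": (45.0, 12.0)}
    )
    tumor_radius_range: tuple[int, int] = (5, 9)
    seed: int = 0

    def noise_sd_vector(self) -> np.ndarray:
        sd = np.broadcast_to(np.asarray(self.noise_sd, dtype=float), (N_CHANNELS,))
        return np.array(sd, dtype=float)

    def validate(self) -> None:
        if not 0.0 < self.class_balance < 1.0:
            raise ValueError("class_balance must lie in (0, 1)")
        if self.n_subjects < 4:
            raise ValueError("need at least 2 subjects per class (LOOCV undefined otherwise)")
        if len(self.volume_shape) != 3 or any(d < 8 for d in self.volume_shape):
            raise ValueError("volume_shape must be three dimensions of at least 8 voxels")
        if np.any(self.noise_sd_vector() < 0):
            raise ValueError("noise_sd must be non-negative")
        if not 0.0 <= self.t2_adc_rho <= 1.0:
            raise ValueError("t2_adc_rho must lie in [0, 1]")
        for g in GENOTYPES:
            fh, fp = self.focus_fraction_by_class[g]
            if fh < 0 or fp < 0 or fh + fp > 1.0:
                raise ValueError(
                    f"focus fractions for {g} must be non-negative and sum to <= 1"
                )
            if self.age_params[g][1] < 0:
                raise ValueError("age SD must be non-negative")
        rmin, rmax = self.tumor_radius_range
        if rmin < 1 or rmax < rmin:
            raise ValueError("tumor_radius_range must satisfy 1 <= rmin <= rmax")


@dataclass
class SyntheticSubject:
    """A generated study plus its ground-truth compartment map."""

    study: MultiparametricStudy
    compartment_map: np.ndarray

    def focus_fraction(self) -> float:
        """Empirical fraction of tumor voxels inside either focus."""
        tumor = self.study.tumor_mask
        focal = np.isin(self.compartment_map, (HYPERMETABOLIC_FOCUS, PERFUSION_FOCUS))
        return float(np.count_nonzero(focal & tumor) / np.count_nonzero(tumor))


def _sphere_mask(shape: tuple[int, int, int], center: np.ndarray, radius: float) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, d) for d in shape)]
    d2 = sum((g - c) ** 2 for g, c in zip(grids, center))
    return d2 <= radius**2


def _brain_geometry(shape: tuple[int, int, int]) -> tuple[np.ndarray, float]:
    center = (np.asarray(shape) - 1) / 2.0
    radius = min(shape) / 2.0 - 1.5
    return center, radius


def _grow_blob(allowed: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    """Grow a 6-connected blob of `size` voxels inside the allowed mask."""
    out = np.zeros_like(allowed)
    if size <= 0:
        return out
    candidates = np.argwhere(allowed)
    start = tuple(candidates[rng.integers(len(candidates))])
    frontier = deque([start])
    seen = {start}
    taken = 0
    shape = allowed.shape
    offsets = [(1, 0, 0), (-1, 0, 0), (0, 1, 0), (0, -1, 0), (0, 0, 1), (0, 0, -1)]
    while frontier and taken < size:
        # randomized frontier pop keeps blob shapes irregular but seeded
        idx = rng.integers(len(frontier))
        frontier.rotate(-idx)
        vox = frontier.popleft()
        if not allowed[vox] or out[vox]:
            continue
        out[vox] = True
        taken += 1
        for off in offsets:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            if all(0 <= nb[a] < shape[a] for a in range(3)) and nb not in seen:
                seen.add(nb)
                if allowed[nb] and not out[nb]:
                    frontier.append(nb)
    return out


def subject_rng(spec: CohortSpec, index: int) -> np.random.Generator:
    """Counter-based per-subject stream: independent of generation order."""
    return np.random.default_rng(np.random.SeedSequence(spec.seed, spawn_key=(index,)))


def generate_subject(
    spec: CohortSpec,
    genotype: str,
    rng: np.random.Generator,
    subject_id: str = "subject_000",
) -> SyntheticSubject:
    """Generate one subject of the given genotype from an RNG stream."""
    spec.validate()
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}")
    shape = tuple(spec.volume_shape)
    brain_center, brain_radius = _brain_geometry(shape)

    radius = int(rng.integers(spec.tumor_radius_range[0], spec.tumor_radius_range[1] + 1))
    for axis, dim in enumerate(shape):
        if 2 * radius + 1 > dim:
            raise ValueError(
                f"tumor radius {radius} exceeds volume bounds along dimension {axis} "
                f"(size {dim})"
            )
    if radius >= brain_radius:
        raise ValueError(
            f"tumor radius {radius} does not fit inside the brain "
            f"(brain radius {brain_radius:.1f}); enlarge dimension 0"
        )

    brain = _sphere_mask(shape, brain_center, brain_radius)
    # tumor center uniform in the brain ball eroded by the tumor radius
    max_offset = brain_radius - radius - 0.5
    while True:
        offset = rng.uniform(-max_offset, max_offset, size=3)
        if np.sum(offset**2) <= max_offset**2:
            break
    tumor_center = brain_center + offset
    tumor = _sphere_mask(shape, tumor_center, radius) & brain
    n_tumor = int(np.count_nonzero(tumor))

    frac_hyper, frac_perf = spec.focus_fraction_by_class[genotype]
    n_hyper = int(rng.binomial(n_tumor, frac_hyper))
    n_perf = int(rng.binomial(n_tumor, frac_perf))
    hyper = _grow_blob(tumor, n_hyper, rng)
    perf = _grow_blob(tumor & ~hyper, min(n_perf, n_tumor - n_hyper), rng)

    compartments = np.full(shape, BACKGROUND, dtype=np.int16)
    compartments[brain] = NORMAL_BRAIN
    compartments[tumor] = TUMOR_BULK
    compartments[hyper] = HYPERMETABOLIC_FOCUS
    compartments[perf] = PERFUSION_FOCUS

    means = np.zeros((5, N_CHANNELS))
    for cid, name in COMPARTMENT_NAMES.items():
        means[cid] = np.asarray(spec.compartment_means[name], dtype=float)
    channels = means[compartments].transpose(3, 0, 1, 2).astype(float)

    sd = spec.noise_sd_vector()
    if np.any(sd > 0):
        noise = rng.standard_normal((N_CHANNELS,) + shape)
        # T2 and ADC share a latent field: split their noise into a common
        # component (weight sqrt(rho)) and independent remainders
        shared = rng.standard_normal(shape)
        rho = spec.t2_adc_rho
        for c in (CHANNEL_NAMES.index("t2"), CHANNEL_NAMES.index("adc")):
            noise[c] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * noise[c]
        channels[:, brain] += sd[:, None] * noise[:, brain]

    age_mean, age_sd = spec.age_params[genotype]
    age = float(np.clip(rng.normal(age_mean, age_sd), 18.0, 90.0))

    study = MultiparametricStudy(
        subject_id=subject_id,
        channels=channels,
        brain_mask=brain,
        tumor_mask=tumor,
        genotype=genotype,
        age=age,
    )
    study.validate()
    return SyntheticSubject(study=study, compartment_map=compartments)


def genotype_sequence(spec: CohortSpec) -> list[str]:
    """Deterministic genotype assignment honoring the class balance."""
    n_wt = int(round(spec.n_subjects * spec.class_balance))
    n_mut = spec.n_subjects - n_wt
    if n_wt < 2 or n_mut < 2:
        raise ValueError(
            f"class balance {spec.class_balance:.3f} leaves fewer than 2 subjects "
            "in one class; LOOCV is undefined"
        )
    return ["wildtype"] * n_wt + ["mutant"] * n_mut


def generate_cohort(spec: CohortSpec) -> tuple[list[SyntheticSubject], pd.DataFrame]:
    """Generate all subjects plus a manifest table.

    Subjects are drawn from counter-based per-subject RNG streams derived
    from the cohort seed, so any subject can be regenerated independently.
    """
    spec.validate()
    genotypes = genotype_sequence(spec)
    subjects = []
    rows = []
    for i, genotype in enumerate(genotypes):
        sid = f"sub-{i:03d}"
        subj = generate_subject(spec, genotype, subject_rng(spec, i), subject_id=sid)
        subjects.append(subj)
        row = {"subject_id": sid, "genotype": genotype, "age": subj.study.age}
        for name in CHANNEL_NAMES:
            row[f"path_{name}"] = f"{sid}/{name}.nii.gz"
        row["path_brain"] = f"{sid}/brain_mask.nii.gz"
        row["path_tumor"] = f"{sid}/tumor_mask.nii.gz"
        rows.append(row)
    return subjects, pd.DataFrame(rows)


def _save_nifti(arr: np.ndarray, path: Path) -> None:
    img = nib.Nifti1Image(np.asarray(arr), affine=np.eye(4))
    nib.save(img, str(path))


def write_cohort(
    cohort: tuple[list[SyntheticSubject], pd.DataFrame],
    directory: str | Path,
    overwrite: bool = False,
) -> Path:
    """Write NIfTI volumes, masks, ground-truth maps, and the manifest CSV."""
    subjects, manifest = cohort
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest_path = directory / "manifest.csv"
    if manifest_path.exists() and not overwrite:
        raise FileExistsError(f"{manifest_path} exists; pass overwrite=True to replace")
    for subj, (_, row) in zip(subjects, manifest.iterrows()):
        sdir = directory / row["subject_id"]
        sdir.mkdir(exist_ok=True)
        for c, name in enumerate(CHANNEL_NAMES):
            target = directory / row[f"path_{name}"]
            if target.exists() and not overwrite:
                raise FileExistsError(f"{target} exists; pass overwrite=True to replace")
            _save_nifti(subj.study.channels[c], target)
        _save_nifti(subj.study.brain_mask.astype(np.uint8), directory / row["path_brain"])
        _save_nifti(subj.study.tumor_mask.astype(np.uint8), directory / row["path_tumor"])
        _save_nifti(subj.compartment_map.astype(np.int16), sdir / "compartments.nii.gz")
    manifest.to_csv(manifest_path, index=False)
    return manifest_path


def read_cohort(manifest_path: str | Path) -> list[MultiparametricStudy]:
    """Load studies from a manifest CSV written by :func:`write_cohort`."""
    manifest_path = Path(manifest_path)
    root = manifest_path.parent
    manifest = pd.read_csv(manifest_path)
    studies = []
    for _, row in manifest.iterrows():
        channels = np.stack(
            [np.asarray(nib.load(str(root / row[f"path_{name}"])).dataobj, dtype=float)
             for name in CHANNEL_NAMES]
        )
        brain = np.asarray(nib.load(str(root / row["path_brain"])).dataobj) > 0
        tumor = np.asarray(nib.load(str(root / row["path_tumor"])).dataobj) > 0
        study = MultiparametricStudy(
            subject_id=row["subject_id"],
            channels=channels,
            brain_mask=brain,
            tumor_mask=tumor,
            genotype=row["genotype"],
            age=float(row["age"]),
        )
        study.validate()
        studies.append(study)
    return studies


def null_spec(spec: CohortSpec, fractions: tuple[float, float] = (0.15, 0.10)) -> CohortSpec:
    """Copy of the spec with the class-conditional focus gap removed.

    Both genotypes receive the same focus fractions, so label-fraction
    features carry no genotype signal (a null cohort for calibration).
    """
    return replace(
        spec,
        focus_fraction_by_class={"wildtype": fractions, "mutant": fractions},
    )
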