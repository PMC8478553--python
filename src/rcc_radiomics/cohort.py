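"""Synthetic multiphase-CT cohort generator.

The original RCC study cohort (261 patients, ccRCC:pRCC:cRCC roughly
209:25:29) is not publicly deposited, so this module generates seeded
synthetic cohorts with the statistical structure the downstream analysis
assumes:

* four contrast phases (NCP, CMP, NP, EP) per subject, with per-subtype
  median lesion attenuations set to the published cohort's values
  (e.g. CMP 105.31 / 53.61 / 85.21 HU for ccRCC / pRCC / cRCC);
* an ellipsoidal lesion on a homogeneous background, textured with a
  Gaussian random field whose correlation length depends on subtype, so
  texture features — not only first-order intensity — carry subtype
  signal;
* optional hypodense (cystic) and hyperdense (calcified) inclusions with
  subtype-dependent frequencies;
* two simulated raters: rater 1 uses the ideal lesion mask eroded by the
  2 mm safety margin that segmentation protocols keep from the tumor
  edge; rater 2 is a boundary-perturbed copy;
* a clinical covariate table whose categorical frequencies follow the
  published per-subtype proportions, with lesion attenuations recomputed
  from the generated voxels.

Everything is deterministic given ``CohortConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

PHASES = ("NCP", "CMP", "NP", "EP")
SUBTYPES = ("ccRCC", "pRCC", "cRCC")

#: Published per-subtype median lesion attenuation (HU) per phase.
MEDIAN_LESION_HU = {
    "ccRCC": {"NCP": 33.89, "CMP": 105.31, "NP": 86.98, "EP": 69.93},
    "pRCC": {"NCP": 35.35, "CMP": 53.61, "NP": 61.90, "EP": 60.71},
    "cRCC": {"NCP": 26.61, "CMP": 85.21, "NP": 77.81, "EP": 65.95},
}

#: Published per-subtype clinical category probabilities (from the
#: cohort characteristics table; probabilities are count ratios).
CLINICAL_PROFILE = {
    "ccRCC": {
        "male": 136 / 207,
        "right": 114 / 207,
        "symptoms": 116 / 207,
        "growth": {"outside": 70 / 207, "middle": 90 / 207, "inside": 47 / 207},
        "t_stage": {"T1": 144 / 207, "T2": 25 / 207, "T3": 17 / 207, "T4": 21 / 207},
        "n1": 22 / 208,
        "m1": 13 / 207,
        "age_median": 52.0,
    },
    "pRCC": {
        "male": 18 / 25,
        "right": 10 / 25,
        "symptoms": 15 / 25,
        "growth": {"outside": 7 / 25, "middle": 10 / 25, "inside": 8 / 25},
        "t_stage": {"T1": 15 / 25, "T2": 5 / 25, "T3": 2 / 25, "T4": 3 / 25},
        "n1": 6 / 25,
        "m1": 2 / 25,
        "age_median": 52.0,
    },
    "cRCC": {
        "male": 12 / 29,
        "right": 13 / 29,
        "symptoms": 12 / 29,
        "growth": {"outside": 10 / 29, "middle": 13 / 29, "inside": 6 / 29},
        "t_stage": {"T1": 21 / 29, "T2": 6 / 29, "T3": 1 / 29, "T4": 1 / 29},
        "n1": 1 / 29,
        "m1": 2 / 29,
        "age_median": 54.0,
    },
}


class ConfigurationError(ValueError):
    """Raised for invalid cohort configurations."""


@dataclass(frozen=True)
class PhaseVolume:
    """One CT phase of one subject: HU voxels on a regular grid."""

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    phase: str

    def __post_init__(self):
        if self.phase not in PHASES:
            raise ConfigurationError(f"unknown phase {self.phase!r}")
        if not all(s > 0 for s in self.spacing):
            raise ConfigurationError("spacing must be strictly positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ConfigurationError("non-finite voxel values")


@dataclass(frozen=True)
class RaterMask:
    """A rater's binary lesion segmentation."""

    voxels: np.ndarray
    rater_id: int

    def __post_init__(self):
        if self.rater_id not in (1, 2):
            raise ConfigurationError("rater_id must be 1 or 2")
        if not np.any(self.voxels):
            raise ConfigurationError("mask has no foreground voxel")

    @property
    def volume_voxels(self) -> int:
        return int(np.count_nonzero(self.voxels))


@dataclass
class ClinicalRecord:
    """Per-subject clinical covariates (cohort-characteristics style)."""

    sex: str
    age: float
    side: str
    diameter_mm: float
    symptoms: str
    growth: str
    cystic: str
    calcification: str
    t_stage: str
    n_stage: str
    m_stage: str
    tnm_stage: str
    attenuation: dict[str, float] = field(default_factory=dict)


@dataclass
class Subject:
    """One synthetic patient: 4 phase volumes, 2 rater masks, clinical data.

    The same pair of masks applies to every phase (the lesion geometry is
    shared, mirroring the protocol of reusing the CMP segmentation for
    the NCP image).
    """

    id: str
    subtype: str
    volumes: dict[str, PhaseVolume]
    masks: dict[int, RaterMask]
    clinical: ClinicalRecord | None = None

    def __post_init__(self):
        if self.subtype not in SUBTYPES:
            raise ConfigurationError(f"unknown subtype {self.subtype!r}")
        if set(self.volumes) != set(PHASES):
            raise ConfigurationError("subject must have exactly the 4 phases")
        if set(self.masks) != {1, 2}:
            raise ConfigurationError("subject must have exactly 2 rater masks")


@dataclass
class CohortConfig:
    """Generator settings; defaults mirror the published study cohort."""

    counts: dict[str, int] = field(
        default_factory=lambda: {"ccRCC": 209, "pRCC": 25, "cRCC": 29}
    )
    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    mean_hu: dict[str, dict[str, float]] = field(
        default_factory=lambda: {s: dict(MEDIAN_LESION_HU[s]) for s in SUBTYPES}
    )
    background_hu: float = -20.0
    background_noise_sd: float = 5.0
    between_subject_sd: float = 12.0
    noise_sd: float = 15.0
    #: Gaussian smoothing sigma (voxels) of the lesion random field —
    #: the subtype-specific texture correlation length.
    texture_sigma: dict[str, float] = field(
        default_factory=lambda: {"ccRCC": 2.5, "pRCC": 1.0, "cRCC": 4.0}
    )
    #: per-subject, per-phase jitter (SD, voxels) of the correlation
    #: length: tumor texture varies between patients and acquisitions,
    #: so each phase carries partly independent texture information.
    texture_sigma_sd: float = 0.5
    #: lesion semi-axes drawn uniformly in this fraction of the grid size
    radius_frac: tuple[float, float] = (0.25, 0.40)
    margin_mm: float = 2.0
    rater_magnitude: int = 1
    cystic_prob: dict[str, float] = field(
        default_factory=lambda: {"ccRCC": 161 / 207, "pRCC": 11 / 25, "cRCC": 9 / 29}
    )
    calcification_prob: dict[str, float] = field(
        default_factory=lambda: {"ccRCC": 42 / 204, "pRCC": 4 / 25, "cRCC": 2 / 29}
    )
    cystic_delta_hu: float = -45.0
    calcification_delta_hu: float = 180.0
    inclusion_frac: float = 0.30  # inclusion semi-axes / lesion semi-axes
    seed: int = 0

    def validate(self) -> None:
        if set(self.counts) - set(SUBTYPES):
            raise ConfigurationError(f"unknown subtype in counts: {self.counts}")
        if any(c < 0 for c in self.counts.values()):
            raise ConfigurationError("counts must be >= 0")
        if sum(self.counts.values()) < 1:
            raise ConfigurationError("total cohort size must be >= 1")
        if any(n <= 0 for n in self.shape) or len(self.shape) != 3:
            raise ConfigurationError("grid shape must be positive 3D")
        if any(s <= 0 for s in self.spacing):
            raise ConfigurationError("spacing must be positive")
        for probs in (self.cystic_prob, self.calcification_prob):
            if any(not 0 <= p <= 1 for p in probs.values()):
                raise ConfigurationError("probabilities must lie in [0, 1]")
        if not 0 < self.radius_frac[0] <= self.radius_frac[1] < 0.5:
            raise ConfigurationError("radius_frac must satisfy 0 < lo <= hi < 0.5")
        if self.rater_magnitude < 0:
            raise ConfigurationError("rater_magnitude must be >= 0")

    def margin_voxels(self) -> int:
        return int(round(self.margin_mm / min(self.spacing)))


# ---------------------------------------------------------------------------
# geometry and volumes


def _ellipsoid_mask(shape, center, semi_axes) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    acc = np.zeros(shape, dtype=float)
    for g, c, a in zip(grids, center, semi_axes):
        acc += ((g - c) / a) ** 2
    return acc <= 1.0


def _draw_geometry(cfg: CohortConfig, rng: np.random.Generator):
    """Lesion ellipsoid semi-axes (voxels), centered on the grid."""
    lo, hi = cfg.radius_frac
    dims = np.asarray(cfg.shape, dtype=float)
    semi = rng.uniform(lo, hi, size=3) * dims.min()
    center = (dims - 1) / 2.0
    return center, semi


def generate_lesion_volume(
    subtype: str,
    phase: str,
    cfg: CohortConfig | None = None,
    seed: int = 0,
    *,
    rng: np.random.Generator | None = None,
    geometry=None,
    target_mean: float | None = None,
    cystic: bool = False,
    calcification: bool = False,
    texture_sigma: float | None = None,
):
    """Generate one phase volume and its ideal lesion mask.

    The lesion is an ellipsoid whose voxel mean equals ``target_mean``
    (default: the configured per-subtype per-phase mean) exactly after
    recentring the textured field; the background sits on a distinct HU
    plateau.  Returns ``(PhaseVolume, ideal_mask)``.
    """
    cfg = cfg or CohortConfig()
    cfg.validate()
    if subtype not in SUBTYPES:
        raise ConfigurationError(f"unknown subtype {subtype!r}")
    if phase not in PHASES:
        raise ConfigurationError(f"unknown phase {phase!r}")
    rng = rng if rng is not None else np.random.default_rng(seed)
    if geometry is None:
        geometry = _draw_geometry(cfg, rng)
    center, semi = geometry
    if any(2 * a >= n for a, n in zip(semi, cfg.shape)):
        raise ConfigurationError("lesion larger than grid")
    mask = _ellipsoid_mask(cfg.shape, center, semi)
    if target_mean is None:
        target_mean = cfg.mean_hu[subtype][phase]

    vox = np.full(cfg.shape, cfg.background_hu, dtype=float)
    if cfg.background_noise_sd > 0:
        vox += rng.normal(0.0, cfg.background_noise_sd, size=cfg.shape)

    if texture_sigma is None:
        texture_sigma = cfg.texture_sigma[subtype]
    lesion = np.full(cfg.shape, float(target_mean))
    if cfg.noise_sd > 0:
        field_ = ndimage.gaussian_filter(
            rng.normal(size=cfg.shape), sigma=max(texture_sigma, 0.3)
        )
        sd = field_[mask].std()
        if sd > 0:
            lesion += field_ * (cfg.noise_sd / sd)

    # inclusions sit off-center (cystic change and calcifications are
    # typically eccentric), which also keeps the central solid tissue —
    # what the attenuation measurements sample — close to the target
    def _offcenter():
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        return center + u * rng.uniform(0.45, 0.7) * semi

    if cystic:
        inc = _ellipsoid_mask(cfg.shape, _offcenter(), semi * cfg.inclusion_frac)
        lesion[inc & mask] += cfg.cystic_delta_hu
    if calcification:
        inc = _ellipsoid_mask(cfg.shape, _offcenter(), semi * cfg.inclusion_frac * 0.4)
        lesion[inc & mask] += cfg.calcification_delta_hu

    # recentre so the measured lesion attenuation equals the target
    # exactly: the reference region is the margin-eroded core, which is
    # what the exported rater masks (and hence the clinical attenuation
    # column) sample
    margin = cfg.margin_voxels()
    core = ndimage.binary_erosion(mask, iterations=margin) if margin else mask
    if not core.any():
        core = mask
    lesion[mask] += target_mean - lesion[core].mean()
    vox[mask] = lesion[mask]
    return PhaseVolume(voxels=vox, spacing=cfg.spacing, phase=phase), mask


def perturb_mask(mask: RaterMask, magnitude: int, seed: int = 0) -> RaterMask:
    """Simulate a second rater by randomly toggling boundary voxels.

    Performs ``magnitude`` passes; in each pass boundary voxels (inner
    and outer one-voxel shells) are flipped independently with
    probability 0.3.  Voxels deeper than ``magnitude`` from the surface
    are untouched.  ``magnitude = 0`` returns an identical mask.
    """
    if magnitude < 0:
        raise ConfigurationError("magnitude must be >= 0")
    rng = np.random.default_rng(seed)
    m = np.asarray(mask.voxels).astype(bool).copy()
    for _ in range(magnitude):
        inner = m & ~ndimage.binary_erosion(m)
        outer = ndimage.binary_dilation(m) & ~m
        flip = (inner | outer) & (rng.random(m.shape) < 0.3)
        m ^= flip
    if not m.any():  # pathological shrink of a tiny mask
        m = np.asarray(mask.voxels).astype(bool).copy()
    return RaterMask(voxels=m, rater_id=2)


# ---------------------------------------------------------------------------
# clinical covariates


def _choice(rng, options, probs):
    probs = np.asarray(probs, dtype=float)
    return options[rng.choice(len(options), p=probs / probs.sum())]


def _tnm_stage(t: str, n: str, m: str) -> str:
    if m == "M1" or t == "T4":
        return "IV"
    if n == "N1" or t == "T3":
        return "III"
    if t == "T2":
        return "II"
    return "I"


def _draw_clinical(subtype: str, cfg: CohortConfig, rng, cystic: bool, calcified: bool,
                   diameter_mm: float) -> ClinicalRecord:
    prof = CLINICAL_PROFILE[subtype]
    t = _choice(rng, list(prof["t_stage"]), list(prof["t_stage"].values()))
    n = "N1" if rng.random() < prof["n1"] else "N0"
    m = "M1" if rng.random() < prof["m1"] else "M0"
    return ClinicalRecord(
        sex="male" if rng.random() < prof["male"] else "female",
        age=float(np.clip(rng.normal(prof["age_median"], 12.0), 18, 90)),
        side="right" if rng.random() < prof["right"] else "left",
        diameter_mm=diameter_mm,
        symptoms="+" if rng.random() < prof["symptoms"] else "-",
        growth=_choice(rng, list(prof["growth"]), list(prof["growth"].values())),
        cystic="+" if cystic else "-",
        calcification="+" if calcified else "-",
        t_stage=t,
        n_stage=n,
        m_stage=m,
        tnm_stage=_tnm_stage(t, n, m),
    )


# ---------------------------------------------------------------------------
# cohort assembly


def _generate_subject(subject_id: str, subtype: str, cfg: CohortConfig,
                      rng: np.random.Generator) -> Subject:
    geometry = _draw_geometry(cfg, rng)
    cystic = rng.random() < cfg.cystic_prob[subtype]
    calcified = rng.random() < cfg.calcification_prob[subtype]
    offsets = {ph: rng.normal(0.0, cfg.between_subject_sd) for ph in PHASES}

    volumes = {}
    ideal = None
    for ph in PHASES:
        vol, ideal = generate_lesion_volume(
            subtype,
            ph,
            cfg,
            rng=rng,
            geometry=geometry,
            target_mean=cfg.mean_hu[subtype][ph] + offsets[ph],
            cystic=cystic,
            calcification=calcified,
            texture_sigma=cfg.texture_sigma[subtype]
            + rng.normal(0.0, cfg.texture_sigma_sd),
        )
        volumes[ph] = vol

    margin = cfg.margin_voxels()
    r1 = ndimage.binary_erosion(ideal, iterations=margin) if margin else ideal
    if not r1.any():
        r1 = ideal
    mask1 = RaterMask(voxels=r1, rater_id=1)
    mask2 = perturb_mask(mask1, cfg.rater_magnitude,
                         seed=int(rng.integers(0, 2**31)))

    diameter_mm = float(2 * max(geometry[1]) * min(cfg.spacing))
    clinical = _draw_clinical(subtype, cfg, rng, cystic, calcified, diameter_mm)
    return Subject(id=subject_id, subtype=subtype, volumes=volumes,
                   masks={1: mask1, 2: mask2}, clinical=clinical)


def generate_cohort(cfg: CohortConfig | None = None) -> list[Subject]:
    """Generate the configured cohort, deterministically from ``cfg.seed``.

    Subjects are ordered ccRCC block, pRCC block, cRCC block, with ids
    ``S0001``…; each subject has its own random substream so cohorts of
    different sizes share their leading subjects.
    """
    cfg = cfg or CohortConfig()
    cfg.validate()
    n_total = sum(cfg.counts.get(s, 0) for s in SUBTYPES)
    children = np.random.SeedSequence(cfg.seed).spawn(n_total)
    subjects = []
    idx = 0
    for subtype in SUBTYPES:
        for _ in range(cfg.counts.get(subtype, 0)):
            rng = np.random.default_rng(children[idx])
            subjects.append(_generate_subject(f"S{idx + 1:04d}", subtype, cfg, rng))
            idx += 1
    return subjects


def lesion_mean_hu(subject: Subject, phase: str, rater: int = 1) -> float:
    """Mean HU of the lesion voxels inside the given rater's mask."""
    return float(subject.volumes[phase].voxels[subject.masks[rater].voxels].mean())


def generate_clinical_table(cohort: list[Subject]) -> pd.DataFrame:
    """Assemble the clinical covariate table of a generated cohort.

    Lesion attenuations are recomputed from the subject's own voxels
    (mean HU inside the rater-1 mask), not sampled.
    """
    if not cohort:
        raise ConfigurationError("cohort is empty")
    rows = []
    for s in cohort:
        rec = dataclasses.asdict(s.clinical)
        rec.pop("attenuation", None)
        rec.update({f"att_{ph.lower()}": lesion_mean_hu(s, ph) for ph in PHASES})
        s.clinical.attenuation = {ph: rec[f"att_{ph.lower()}"] for ph in PHASES}
        rows.append({"subject_id": s.id, "subtype": s.subtype, **rec})
    return pd.DataFrame(rows).set_index("subject_id")


# ---------------------------------------------------------------------------
# on-disk representation (NIfTI + CSV + JSON manifest)


def write_cohort(cohort: list[Subject], outdir: str | Path) -> Path:
    """Write volumes/masks as .nii.gz, the clinical table as CSV, and a
    JSON manifest mapping subject ids to file paths.  Returns the
    manifest path."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"subjects": {}}
    for s in cohort:
        entry = {"subtype": s.subtype, "volumes": {}, "masks": {}}
        affine = np.diag(list(s.volumes["CMP"].spacing) + [1.0])
        for ph, vol in s.volumes.items():
            p = outdir / f"{s.id}_{ph}.nii.gz"
            nib.save(nib.Nifti1Image(vol.voxels.astype(np.float32), affine), p)
            entry["volumes"][ph] = p.name
        for rid, m in s.masks.items():
            p = outdir / f"{s.id}_mask_r{rid}.nii.gz"
            nib.save(nib.Nifti1Image(m.voxels.astype(np.uint8), affine), p)
            entry["masks"][str(rid)] = p.name
        manifest["subjects"][s.id] = entry
    generate_clinical_table(cohort).to_csv(outdir / "clinical.csv")
    manifest["clinical_table"] = "clinical.csv"
    manifest_path = outdir / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest_path


def read_cohort(outdir: str | Path) -> list[Subject]:
    """Reload a cohort written by :func:`write_cohort`."""
    import nibabel as nib

    outdir = Path(outdir)
    manifest = json.loads((outdir / "manifest.json").read_text())
    clinical = pd.read_csv(outdir / manifest["clinical_table"], index_col=0)
    subjects = []
    for sid, entry in manifest["subjects"].items():
        volumes = {}
        for ph, fname in entry["volumes"].items():
            img = nib.load(outdir / fname)
            spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
            volumes[ph] = PhaseVolume(
                voxels=np.asarray(img.dataobj, dtype=float), spacing=spacing, phase=ph
            )
        masks = {
            int(rid): RaterMask(
                voxels=np.asarray(nib.load(outdir / fname).dataobj) > 0.5,
                rater_id=int(rid),
            )
            for rid, fname in entry["masks"].items()
        }
        row = clinical.loc[sid]
        rec = ClinicalRecord(
            sex=row["sex"], age=row["age"], side=row["side"],
            diameter_mm=row["diameter_mm"], symptoms=row["symptoms"],
            growth=row["growth"], cystic=row["cystic"],
            calcification=row["calcification"], t_stage=row["t_stage"],
            n_stage=row["n_stage"], m_stage=row["m_stage"],
            tnm_stage=row["tnm_stage"],
            attenuation={ph: float(row[f"att_{ph.lower()}"]) for ph in PHASES},
        )
        subjects.append(Subject(id=sid, subtype=entry["subtype"],
                                volumes=volumes, masks=masks, clinical=rec))
    return subjects
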