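"""Digital lesion phantoms and synthetic cohorts.

The generator mimics a head-and-neck quantitative-MRI protocol: a
five-b-value DWI acquisition (0, 500, 1000, 1500, 2000 s/mm^2) whose
signal averages increase with b (NEX 4 below 1500 s/mm^2, 8 above) and a
70-frame DCE series at 5 s resolution with three pre-contrast baselines.
A phantom is an ellipsoidal lesion with smoothly varying ground-truth
maps of S0, D, K, Ktrans and kep; forward simulation produces magnitude
DWI with Rician noise (scale sigma/sqrt(NEX) per b-value) and a DCE
signal series driven by the Tofts model.

Cohorts attach pathology labels to each lesion.  Tumor-infiltrating
lymphocytes (TILs) are coupled to the lesion's diffusion truth through a
Gaussian copula so that the population Spearman correlations with D
(negative) and K (positive) can be planted directly; the categorical
factors are drawn from fixed marginal frequencies typical of an oral
squamous-cell-carcinoma series.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml
from scipy import ndimage
from scipy.special import ndtr

from .dce import AIF, ConversionSettings, _tofts_batch, concentration_to_signal, population_aif
from .dki import D_BOUNDS_DEFAULT, K_BOUNDS_DEFAULT, dki_signal


@dataclass(frozen=True)
class AcquisitionConfig:
    """Acquisition geometry and noise of the simulated protocol."""

    b_values: tuple[float, ...] = (0.0, 500.0, 1000.0, 1500.0, 2000.0)
    nex_per_b: tuple[int, ...] = (4, 4, 4, 8, 8)
    dce_n_volumes: int = 70
    dce_dt: float = 5.0  # seconds
    dce_baseline_volumes: int = 3
    noise_sigma: float = 0.0  # Rician scale at NEX=1, signal units
    seed: int = 0

    def __post_init__(self) -> None:
        b = np.asarray(self.b_values, dtype=float)
        if b[0] != 0.0 or np.any(np.diff(b) <= 0):
            raise ValueError("b_values must be strictly increasing and start at 0")
        if len(self.nex_per_b) != b.size or any(n < 1 for n in self.nex_per_b):
            raise ValueError("nex_per_b must match b_values with all entries >= 1")
        if not 0 <= self.dce_baseline_volumes < self.dce_n_volumes:
            raise ValueError("dce_baseline_volumes must be < dce_n_volumes")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be nonnegative")

    @property
    def dce_times_min(self) -> np.ndarray:
        """DCE frame times in minutes."""
        return np.arange(self.dce_n_volumes) * self.dce_dt / 60.0

    @property
    def bolus_arrival_min(self) -> float:
        return self.dce_baseline_volumes * self.dce_dt / 60.0


@dataclass(frozen=True)
class LesionSpec:
    """Geometry and heterogeneity of a simulated lesion.

    Mean parameter values sit at plausible tumor levels (D 1.4e-3 mm^2/s,
    K 0.75, kep 2.08 min^-1, ve 0.70, giving Ktrans = kep*ve ~ 1.46);
    ``heterogeneity`` is the fractional standard deviation of the smooth
    intra-lesion texture applied to every map.
    """

    grid_shape: tuple[int, int, int] = (16, 16, 10)
    spacing: tuple[float, float, float] = (2.0, 2.0, 4.0)  # mm
    semi_axes: tuple[float, float, float] = (12.0, 12.0, 16.0)  # mm
    heterogeneity: float = 0.25
    smoothness_vox: float = 1.5
    mean_s0: float = 100.0
    mean_d: float = 1.4e-3
    mean_k: float = 0.75
    mean_kep: float = 2.08
    mean_ve: float = 0.70

    def __post_init__(self) -> None:
        if any(s < 8 for s in self.grid_shape):
            raise ValueError("grid dimensions must be >= 8")
        if self.heterogeneity < 0:
            raise ValueError("heterogeneity must be >= 0")
        extent = [n * d for n, d in zip(self.grid_shape, self.spacing)]
        if any(2 * a > e for a, e in zip(self.semi_axes, extent)):
            raise ValueError(
                f"lesion semi-axes {self.semi_axes} do not fit the "
                f"{extent} mm grid; enlarge grid_shape or shrink the lesion"
            )


@dataclass
class PathologyProfile:
    """Histopathological covariates of one lesion."""

    tils_percent: float
    tsr_percent: float
    grading: str
    keratinization: str
    growth_pattern: str
    necrosis: str
    inflammatory_infiltrate: str
    desmoplastic_reaction: str
    perineural: bool
    vascular_invasion: bool
    tertiary_follicles: str
    cd3_cd20: str
    cd4_cd8: str

    def __post_init__(self) -> None:
        for pct in (self.tils_percent, self.tsr_percent):
            if not 0 <= pct <= 100:
                raise ValueError("percentages must lie in [0, 100]")
        for name, value in (
            ("grading", self.grading),
            ("keratinization", self.keratinization),
            ("growth_pattern", self.growth_pattern),
            ("necrosis", self.necrosis),
            ("inflammatory_infiltrate", self.inflammatory_infiltrate),
            ("desmoplastic_reaction", self.desmoplastic_reaction),
            ("tertiary_follicles", self.tertiary_follicles),
            ("cd3_cd20", self.cd3_cd20),
            ("cd4_cd8", self.cd4_cd8),
        ):
            if value not in PATHOLOGY_LEVELS[name]:
                raise ValueError(f"{name}={value!r} not in {PATHOLOGY_LEVELS[name]}")


PATHOLOGY_LEVELS = {
    "grading": ("well", "moderate", "poor"),
    "keratinization": ("non", "focal", "diffuse"),
    "growth_pattern": ("expansive", "mixed", "infiltrative"),
    "necrosis": ("absent", "focal"),
    "inflammatory_infiltrate": ("mild", "moderate", "intense"),
    "desmoplastic_reaction": ("mild", "moderate", "intense"),
    "tertiary_follicles": ("absent", "rare", "abundant"),
    "cd3_cd20": ("CD3", "CD20", "balanced"),
    "cd4_cd8": ("CD4", "CD8", "balanced"),
}

# Default marginal counts of the categorical factors (missing entries
# dropped); cohorts are drawn from these frequencies.
PATHOLOGY_MARGINALS = {
    "grading": (3, 19, 15),
    "keratinization": (1, 10, 25),
    "growth_pattern": (7, 21, 9),
    "necrosis": (25, 12),
    "inflammatory_infiltrate": (8, 17, 12),
    "desmoplastic_reaction": (12, 12, 12),
    "tertiary_follicles": (14, 17, 6),
    "cd3_cd20": (27, 7, 2),
    "cd4_cd8": (26, 7, 3),
}
_BINARY_MARGINALS = {"perineural": 22 / 37, "vascular_invasion": 5 / 37}


@dataclass
class PhantomTruth:
    """Ground truth of one phantom: grid metadata, lesion mask and
    per-voxel parameter maps (NaN outside the mask)."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float]
    affine: np.ndarray
    lesion_mask: np.ndarray
    maps: dict[str, np.ndarray]  # keys: s0, d, k, ktrans, kep (ve implied)
    pathology: PathologyProfile | None = None

    @property
    def ve_map(self) -> np.ndarray:
        return self.maps["ktrans"] / self.maps["kep"]


def _smooth_field(rng, shape, smoothness, mask):
    """Smooth unit-scale texture, centred so its in-lesion median is 0.

    Centring on the mask keeps the lesion-level median of every textured
    map exactly at its configured mean, so planted cohort-level couplings
    to the lesion truth are not diluted by texture sampling noise.
    """
    field_ = ndimage.gaussian_filter(rng.standard_normal(shape), smoothness)
    inside = field_[mask]
    sd = inside.std()
    if sd == 0:
        return np.zeros_like(field_)
    return (field_ - np.median(inside)) / sd


def generate_phantom(config: AcquisitionConfig, lesion_spec: LesionSpec | None = None) -> PhantomTruth:
    """Build an ellipsoidal lesion phantom with smooth truth maps.

    Deterministic for a fixed ``config.seed``.  Maps are clipped to sit
    strictly inside the physiological fitting bounds so that noiseless
    forward-inverse round trips are exact.
    """
    spec = lesion_spec or LesionSpec()
    rng = np.random.default_rng(config.seed)
    shape = spec.grid_shape
    spacing = np.asarray(spec.spacing, dtype=float)
    affine = np.diag(np.append(spacing, 1.0))

    center = (np.asarray(shape) - 1) / 2.0 * spacing
    coords = np.stack(
        np.meshgrid(*[np.arange(n) * d for n, d in zip(shape, spacing)], indexing="ij"),
        axis=-1,
    )
    rel = (coords - center) / np.asarray(spec.semi_axes)
    mask = (rel**2).sum(axis=-1) <= 1.0

    h = spec.heterogeneity

    def textured(mean, lo, hi):
        f = _smooth_field(rng, shape, spec.smoothness_vox, mask)
        vals = mean * (1.0 + h * f)
        return np.clip(vals, lo, hi)

    d_lo, d_hi = D_BOUNDS_DEFAULT[0] * 1.1, D_BOUNDS_DEFAULT[1] * 0.95
    k_lo, k_hi = K_BOUNDS_DEFAULT[0] + 0.02, K_BOUNDS_DEFAULT[1] * 0.95
    s0 = textured(spec.mean_s0, 1.0, np.inf)
    d = textured(spec.mean_d, d_lo, d_hi)
    k = textured(spec.mean_k, k_lo, k_hi)
    kep = textured(spec.mean_kep, 0.2, 9.99)
    ve = textured(spec.mean_ve, 0.05, 0.95)
    ktrans = kep * ve

    maps = {}
    for name, arr in (("s0", s0), ("d", d), ("k", k), ("ktrans", ktrans), ("kep", kep)):
        out = np.full(shape, np.nan)
        out[mask] = arr[mask]
        maps[name] = out
    return PhantomTruth(shape=shape, spacing=tuple(spacing), affine=affine,
                        lesion_mask=mask, maps=maps)


def simulate_dwi(truth: PhantomTruth, config: AcquisitionConfig,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Forward-simulate the 4D multi-b DWI volume.

    Noiseless voxel signal follows the DKI model; magnitude (Rician)
    noise is applied with effective scale ``noise_sigma/sqrt(NEX_b)``,
    emulating complex averaging over the NEX repeats.  Background voxels
    are noise-only.
    """
    rng = rng or np.random.default_rng(config.seed + 1)
    b = np.asarray(config.b_values, dtype=float)
    mask = truth.lesion_mask
    clean = np.zeros(truth.shape + (b.size,))
    s0 = truth.maps["s0"][mask]
    d = truth.maps["d"][mask]
    k = truth.maps["k"][mask]
    clean[mask] = dki_signal(s0[:, None], d[:, None], k[:, None], b[None, :])

    if config.noise_sigma == 0:
        return clean
    sigma_b = config.noise_sigma / np.sqrt(np.asarray(config.nex_per_b, dtype=float))
    noisy = np.empty_like(clean)
    for i, sig in enumerate(sigma_b):
        re = clean[..., i] + rng.normal(0.0, sig, size=truth.shape)
        im = rng.normal(0.0, sig, size=truth.shape)
        noisy[..., i] = np.hypot(re, im)
    return noisy


def simulate_dce(truth: PhantomTruth, config: AcquisitionConfig,
                 aif: AIF | None = None,
                 conversion: ConversionSettings | None = None,
                 noise_sigma: float = 0.0,
                 rng: np.random.Generator | None = None) -> np.ndarray:
    """Forward-simulate the 4D DCE signal series.

    Tissue concentration comes from the Tofts model driven by ``aif``
    (default: population AIF with the bolus arriving after the baseline
    frames); concentration is converted to signal with ``conversion``
    and additive Gaussian temporal noise of scale ``noise_sigma``.
    """
    rng = rng or np.random.default_rng(config.seed + 2)
    t = config.dce_times_min
    if aif is None:
        aif = population_aif(t, arrival_min=config.bolus_arrival_min)
    if not np.array_equal(aif.time, t):
        raise ValueError("AIF time grid does not match the DCE sampling")
    conversion = conversion or ConversionSettings(mode="linear", calibration=0.5)

    mask = truth.lesion_mask
    kt = truth.maps["ktrans"][mask]
    kep = truth.maps["kep"][mask]
    ct = _tofts_batch(kt, kep, aif.time, aif.cp)
    s_pre = truth.maps["s0"][mask][:, None]
    series = np.zeros(truth.shape + (t.size,))
    series[mask] = concentration_to_signal(ct, s_pre, conversion)
    if noise_sigma > 0:
        series = series + rng.normal(0.0, noise_sigma, size=series.shape)
    return series


# ---------------------------------------------------------------------------
# cohorts with planted imaging-pathology associations
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class EffectSpec:
    """Planted population Spearman correlations between TILs and the
    lesion-level diffusion truth (negative with D, positive with K)."""

    rho_tils_d: float = -0.393
    rho_tils_k: float = 0.445

    def __post_init__(self) -> None:
        for rho in (self.rho_tils_d, self.rho_tils_k):
            if not -1.0 <= rho <= 1.0:
                raise ValueError("effect strengths must lie in [-1, 1]")
        r = [2 * np.sin(np.pi * rho / 6.0) for rho in (self.rho_tils_d, self.rho_tils_k)]
        if r[0] ** 2 + r[1] ** 2 > 1.0:
            raise ValueError("joint effect strengths exceed a valid correlation structure")


@dataclass
class PatientRecord:
    patient_id: str
    truth: PhantomTruth
    dwi: np.ndarray | None
    dce: np.ndarray | None


# lesion-level truth ranges the copula maps onto (strictly monotone)
_D_RANGE = (0.9e-3, 2.0e-3)
_K_RANGE = (0.45, 1.10)
_TILS_MEDIAN, _TILS_SIGMA = 15.0, 1.121  # lognormal: median 15%, IQR 25%
_TSR_MEAN, _TSR_SD = 65.0, 25.9  # clipped normal: median 65%, IQR 35%


def generate_cohort(n_patients: int,
                    effect_spec: EffectSpec | None = None,
                    seed: int = 0,
                    config: AcquisitionConfig | None = None,
                    lesion_spec: LesionSpec | None = None,
                    simulate: bool = True,
                    simulate_dce_volumes: bool = True) -> list[PatientRecord]:
    """Draw a synthetic cohort with planted TILs-diffusion associations.

    Patient-level latent normals (z_d, z_k) set each lesion's mean D and
    mean K through strictly monotone maps; the TILs latent is a linear
    Gaussian-copula combination of (z_d, z_k) whose weights are chosen so
    the population Spearman correlations equal ``effect_spec``.  With
    ``simulate=False`` only truths and pathology are produced (no image
    volumes), which is enough for truth-level association studies.
    """
    if n_patients < 3:
        raise ValueError("n_patients must be >= 3")
    effect = effect_spec or EffectSpec()
    config = config or AcquisitionConfig()
    spec = lesion_spec or LesionSpec(grid_shape=(10, 10, 8), spacing=(2.0, 2.0, 4.0),
                                     semi_axes=(7.0, 7.0, 10.0))
    rng = np.random.default_rng(seed)

    z_d = rng.standard_normal(n_patients)
    z_k = rng.standard_normal(n_patients)
    eps = rng.standard_normal(n_patients)
    r_d = 2 * np.sin(np.pi * effect.rho_tils_d / 6.0)
    r_k = 2 * np.sin(np.pi * effect.rho_tils_k / 6.0)
    lam = np.sqrt(max(1.0 - r_d**2 - r_k**2, 0.0))
    t_latent = r_d * z_d + r_k * z_k + lam * eps

    tils = np.clip(_TILS_MEDIAN * np.exp(_TILS_SIGMA * t_latent), 0.0, 100.0)
    tsr = np.clip(_TSR_MEAN + _TSR_SD * rng.standard_normal(n_patients), 0.0, 100.0)

    d_mean = _D_RANGE[0] + (_D_RANGE[1] - _D_RANGE[0]) * ndtr(z_d)
    k_mean = _K_RANGE[0] + (_K_RANGE[1] - _K_RANGE[0]) * ndtr(z_k)
    kep_mean = np.clip(2.08 * np.exp(0.30 * rng.standard_normal(n_patients)), 0.5, 8.0)
    ve_mean = np.clip(0.70 + 0.12 * rng.standard_normal(n_patients), 0.25, 0.92)

    records = []
    for i in range(n_patients):
        profile = _draw_pathology(rng, tils[i], tsr[i])
        spec_i = dataclasses.replace(
            spec, mean_d=float(d_mean[i]), mean_k=float(k_mean[i]),
            mean_kep=float(kep_mean[i]), mean_ve=float(ve_mean[i]),
        )
        cfg_i = dataclasses.replace(config, seed=int(rng.integers(2**31)))
        truth = generate_phantom(cfg_i, spec_i)
        truth.pathology = profile
        dwi = dce = None
        if simulate:
            dwi = simulate_dwi(truth, cfg_i, rng=rng)
            if simulate_dce_volumes:
                dce = simulate_dce(truth, cfg_i, rng=rng)
        records.append(PatientRecord(patient_id=f"P{i + 1:03d}", truth=truth,
                                     dwi=dwi, dce=dce))
    return records


def _draw_pathology(rng, tils, tsr) -> PathologyProfile:
    draws = {}
    for factor, counts in PATHOLOGY_MARGINALS.items():
        probs = np.asarray(counts, dtype=float)
        probs /= probs.sum()
        draws[factor] = PATHOLOGY_LEVELS[factor][rng.choice(len(probs), p=probs)]
    return PathologyProfile(
        tils_percent=float(tils), tsr_percent=float(tsr),
        perineural=bool(rng.random() < _BINARY_MARGINALS["perineural"]),
        vascular_invasion=bool(rng.random() < _BINARY_MARGINALS["vascular_invasion"]),
        **draws,
    )


def pathology_frame(records: list[PatientRecord]):
    """Flatten cohort pathology into a pandas DataFrame."""
    import pandas as pd

    rows = []
    for rec in records:
        p = rec.truth.pathology
        row = {"patient_id": rec.patient_id}
        row.update(dataclasses.asdict(p))
        rows.append(row)
    return pd.DataFrame(rows).set_index("patient_id")


# ---------------------------------------------------------------------------
# on-disk layout (NIfTI volumes, FSL-style bvals, YAML config, CSV tables)
# ---------------------------------------------------------------------------

def save_dataset(outdir, truth: PhantomTruth, config: AcquisitionConfig,
                 dwi: np.ndarray | None = None, dce: np.ndarray | None = None) -> None:
    """Write one phantom's volumes and metadata under ``outdir``."""
    import nibabel as nib

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = truth.affine

    def save(arr, name, dtype=np.float32):
        nib.save(nib.Nifti1Image(np.asarray(arr, dtype=dtype), aff), outdir / name)

    save(truth.lesion_mask.astype(np.uint8), "mask.nii.gz", np.uint8)
    for key, arr in truth.maps.items():
        save(arr, f"truth_{key}.nii.gz")
    if dwi is not None:
        save(dwi, "dwi.nii.gz")
        (outdir / "dwi.bval").write_text(
            " ".join(f"{b:g}" for b in config.b_values) + "\n")
    if dce is not None:
        save(dce, "dce.nii.gz")
    (outdir / "config.yaml").write_text(
        yaml.safe_dump(dataclasses.asdict(config), sort_keys=False))


def load_bvals(path) -> np.ndarray:
    """Read an FSL-style whitespace-separated b-value file."""
    return np.asarray(Path(path).read_text().split(), dtype=float)
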