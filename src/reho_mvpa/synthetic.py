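"""Synthetic two-group resting-state cohorts with a controllable group
difference in local temporal synchrony.

Each voxel's series is a mixture of a shared neighborhood signal and private
serially correlated noise,

    x_v(t) = sqrt(rho) * s_region(t) + sqrt(1 - rho) * e_v(t) + drift_v * t,

where s and e are independent unit-variance AR(1) processes and rho is the
region- and group-specific synchrony parameter. Because both components have
unit marginal variance, the expected pairwise temporal correlation between
any two voxels of the same region equals rho exactly (before drift), so the
ReHo ordering between groups is known by construction. The linear drift term
emulates scanner drift and is exactly what the pipeline's detrending step
must cancel.

Cohort defaults mirror a two-group clinical study: 40 subjects per group,
200 retained volumes per run, patient/control ages and symptom-scale scores
drawn from overlapping distributions whose means and SDs match the study the
pipeline reproduces (LSAS total 65.42 +/- 21.23 vs 33.80 +/- 22.01).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .reho import Volume4D, GreyMask, MotionTrace

__all__ = [
    "EffectRegion",
    "SyntheticConfig",
    "PhenotypeDefaults",
    "generate_phenotype",
    "generate_subject_volume",
    "generate_cohort",
    "generate_motion_trace",
    "write_cohort",
]


@dataclass
class EffectRegion:
    """A box in voxel coordinates with group-specific synchrony.

    `box` is ((x0, x1), (y0, y1), (z0, z1)) with exclusive upper bounds.
    """

    box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
    rho_group0: float
    rho_group1: float

    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(lo, hi) for lo, hi in self.box)


# Table-style phenotype parameters: (patient mean, patient sd, control mean, control sd)
@dataclass
class PhenotypeDefaults:
    age: tuple[float, float, float, float] = (25.95, 6.48, 24.80, 3.35)
    lsas_total: tuple[float, float, float, float] = (65.42, 21.23, 33.80, 22.01)
    lsas_fear: tuple[float, float, float, float] = (32.45, 10.39, 15.70, 11.90)
    lsas_avoidance: tuple[float, float, float, float] = (32.47, 11.91, 17.85, 11.34)
    female_fraction: float = 0.35


@dataclass
class SyntheticConfig:
    grid_shape: tuple[int, int, int] = (12, 12, 12)
    n_timepoints: int = 200
    voxel_size_mm: tuple[float, float, float] = (3.0, 3.0, 3.0)
    n_per_group: int = 40
    effect_regions: list[EffectRegion] = field(default_factory=list)
    baseline_rho: float = 0.0
    ar1_coef: float = 0.3
    drift_slope_range: tuple[float, float] = (-0.02, 0.02)
    seed: int = 0
    phenotype: PhenotypeDefaults = field(default_factory=PhenotypeDefaults)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        if len(self.grid_shape) != 3 or any(s <= 0 for s in self.grid_shape):
            raise ValueError(f"grid_shape must be 3 positive integers, got {self.grid_shape}")
        if self.n_timepoints < 10:
            raise ValueError(f"n_timepoints must be >= 10, got {self.n_timepoints}")
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValueError(f"voxel_size_mm must be positive, got {self.voxel_size_mm}")
        if self.n_per_group < 1:
            raise ValueError(f"n_per_group must be >= 1, got {self.n_per_group}")
        if not (0.0 <= self.baseline_rho < 1.0):
            raise ValueError(f"baseline_rho must lie in [0, 1), got {self.baseline_rho}")
        if not (-1.0 < self.ar1_coef < 1.0):
            raise ValueError(f"ar1_coef must lie in (-1, 1), got {self.ar1_coef}")
        if self.drift_slope_range[0] > self.drift_slope_range[1]:
            raise ValueError(f"drift_slope_range must be (lo, hi), got {self.drift_slope_range}")
        for i, reg in enumerate(self.effect_regions):
            if not isinstance(reg, EffectRegion):
                raise ValueError(f"effect_regions[{i}] is not an EffectRegion")
            for rho_name in ("rho_group0", "rho_group1"):
                rho = getattr(reg, rho_name)
                if not (0.0 <= rho < 1.0):
                    raise ValueError(
                        f"effect_regions[{i}].{rho_name} must lie in [0, 1), got {rho}"
                    )
            for axis, (lo, hi) in enumerate(reg.box):
                if not (0 <= lo < hi <= self.grid_shape[axis]):
                    raise ValueError(
                        f"effect_regions[{i}].box axis {axis} bounds ({lo}, {hi}) "
                        f"fall outside grid_shape {self.grid_shape}"
                    )

    @classmethod
    def from_yaml(cls, path) -> "SyntheticConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "SyntheticConfig":
        raw = dict(raw)
        regions = [
            EffectRegion(
                box=tuple(tuple(b) for b in r["box"]),
                rho_group0=float(r["rho_group0"]),
                rho_group1=float(r["rho_group1"]),
            )
            for r in raw.pop("effect_regions", [])
        ]
        pheno = raw.pop("phenotype", None)
        kwargs = {}
        for key in ("grid_shape", "voxel_size_mm", "drift_slope_range"):
            if key in raw:
                kwargs[key] = tuple(raw.pop(key))
        kwargs.update(raw)
        cfg = cls(effect_regions=regions, **kwargs)
        if pheno:
            cfg.phenotype = PhenotypeDefaults(**{
                k: tuple(v) if isinstance(v, (list, tuple)) else v
                for k, v in pheno.items()
            })
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["effect_regions"] = [asdict(r) for r in self.effect_regions]
        return d


def _rho_map(config: SyntheticConfig, group: int) -> tuple[np.ndarray, np.ndarray]:
    """Per-voxel rho for the given group, plus the latent-signal index per
    voxel (0 = cohort-wide background latent, i+1 = effect region i;
    overlapping regions: the last listed wins)."""
    rho = np.full(config.grid_shape, config.baseline_rho, dtype=np.float64)
    latent_idx = np.zeros(config.grid_shape, dtype=np.int64)
    for i, reg in enumerate(config.effect_regions):
        sl = reg.slices()
        rho[sl] = reg.rho_group1 if group == 1 else reg.rho_group0
        latent_idx[sl] = i + 1
    return rho, latent_idx


def _ar1(rng: np.random.Generator, shape: tuple, n: int, a: float) -> np.ndarray:
    """Unit-marginal-variance AR(1) series along the last axis."""
    out = np.empty(shape + (n,), dtype=np.float64)
    out[..., 0] = rng.standard_normal(shape)
    innov_sd = np.sqrt(1.0 - a * a)
    innov = rng.standard_normal(shape + (n - 1,)) * innov_sd
    for t in range(1, n):
        out[..., t] = a * out[..., t - 1] + innov[..., t - 1]
    return out


def generate_subject_volume(
    config: SyntheticConfig, group: int, subject_seed: int,
    subject_id: str = "",
) -> Volume4D:
    """Simulate one subject's 4D volume.

    Deterministic given (config, group, subject_seed); the random draws do
    not depend on `group`, so the two groups differ only through the mixing
    weight sqrt(rho) applied to the shared regional signal.
    """
    config.validate()
    if group not in (0, 1):
        raise ValueError(f"group must be 0 or 1, got {group}")
    rng = np.random.default_rng(subject_seed)
    n = config.n_timepoints
    a = config.ar1_coef
    n_latents = 1 + len(config.effect_regions)

    latents = _ar1(rng, (n_latents,), n, a)
    private = _ar1(rng, config.grid_shape, n, a)
    slopes = rng.uniform(*config.drift_slope_range, size=config.grid_shape)

    rho, latent_idx = _rho_map(config, group)
    shared = latents[latent_idx]  # (x, y, z, n)
    t = np.arange(n, dtype=np.float64)
    data = (
        np.sqrt(rho)[..., None] * shared
        + np.sqrt(1.0 - rho)[..., None] * private
        + slopes[..., None] * t
    )
    return Volume4D(data=data, voxel_size_mm=config.voxel_size_mm,
                    subject_id=subject_id)


def _interior_mask(config: SyntheticConfig) -> GreyMask:
    m = np.zeros(config.grid_shape, dtype=bool)
    if all(s > 2 for s in config.grid_shape):
        m[1:-1, 1:-1, 1:-1] = True
    else:
        m[:] = True
    return GreyMask(data=m, voxel_size_mm=config.voxel_size_mm)


def _truncnorm(rng, mean, sd, size, low):
    vals = rng.normal(mean, sd, size=size)
    return np.clip(vals, low, None)


def _subject_ids(n_per_group: int) -> list[tuple[str, int]]:
    """(subject_id, group) in cohort order: patients first, then controls;
    row k of each block is pair-mate of row k of the other."""
    out = [(f"sub-pat{i + 1:03d}", 1) for i in range(n_per_group)]
    out += [(f"sub-con{i + 1:03d}", 0) for i in range(n_per_group)]
    return out


def generate_phenotype(config: SyntheticConfig, seed: int) -> pd.DataFrame:
    """Phenotype table for a balanced cohort: overlapping age distributions,
    matched sex frequencies, and symptom scores drawn higher in patients."""
    rng = np.random.default_rng(seed)
    p = config.phenotype
    records = []
    for sid, group in _subject_ids(config.n_per_group):
        if group == 1:
            age_m, age_s = p.age[0], p.age[1]
            tot = p.lsas_total[:2]; fear = p.lsas_fear[:2]; avd = p.lsas_avoidance[:2]
        else:
            age_m, age_s = p.age[2], p.age[3]
            tot = p.lsas_total[2:]; fear = p.lsas_fear[2:]; avd = p.lsas_avoidance[2:]
        records.append({
            "subject_id": sid,
            "group": "patient" if group == 1 else "control",
            "age": float(_truncnorm(rng, age_m, age_s, None, 18.0)),
            "sex": "F" if rng.random() < p.female_fraction else "M",
            "lsas_total": float(_truncnorm(rng, tot[0], tot[1], None, 0.0)),
            "lsas_fear": float(_truncnorm(rng, fear[0], fear[1], None, 0.0)),
            "lsas_avoidance": float(_truncnorm(rng, avd[0], avd[1], None, 0.0)),
            "motion_trace_path": "",
        })
    return pd.DataFrame.from_records(records)


def generate_cohort(config: SyntheticConfig):
    """Generate a full balanced cohort.

    Returns (volumes, mask, phenotype DataFrame, ground-truth map). Subjects
    are ordered patients first (group label 1) then controls (label 0);
    phenotype row order defines the default patient-i/control-i pairing of
    the leave-one-pair-out scheme. The grey mask covers the grid minus a
    1-voxel border so every in-mask voxel has a complete 27-neighborhood.
    The ground-truth map marks voxels whose rho differs between groups.
    """
    config.validate()
    ss = np.random.SeedSequence(config.seed)
    n_sub = 2 * config.n_per_group
    subject_seeds = ss.generate_state(n_sub + 1)
    volumes = [
        generate_subject_volume(config, group, int(subject_seeds[i]), subject_id=sid)
        for i, (sid, group) in enumerate(_subject_ids(config.n_per_group))
    ]
    phenotype = generate_phenotype(config, int(subject_seeds[-1]))

    mask = _interior_mask(config)
    truth = np.zeros(config.grid_shape, dtype=np.int16)
    for reg in config.effect_regions:
        if reg.rho_group0 != reg.rho_group1:
            truth[reg.slices()] = 1
    return volumes, mask, phenotype, truth


def generate_motion_trace(
    n_timepoints: int,
    max_translation_mm: float,
    max_rotation_deg: float,
    seed: int,
) -> MotionTrace:
    """Random-walk motion trace whose per-column absolute extrema equal the
    requested maxima exactly (translations in mm, rotations in degrees)."""
    if max_translation_mm < 0 or max_rotation_deg < 0:
        raise ValueError("motion maxima must be >= 0")
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.standard_normal((n_timepoints, 6)), axis=0)
    walk -= walk[0]
    peaks = np.max(np.abs(walk), axis=0)
    scale = np.zeros(6)
    targets = [max_translation_mm] * 3 + [max_rotation_deg] * 3
    for j in range(6):
        scale[j] = targets[j] / peaks[j] if peaks[j] > 0 else 0.0
    return MotionTrace(values=walk * scale)


def write_cohort(config: SyntheticConfig, out_dir,
                 motion_max_mm: float = 0.5, motion_max_deg: float = 0.5):
    """Write a generated cohort to disk: NIfTI volumes, mask, ground truth,
    motion traces, and the phenotype CSV. Returns the phenotype DataFrame."""
    out = Path(out_dir)
    (out / "bold").mkdir(parents=True, exist_ok=True)
    (out / "motion").mkdir(exist_ok=True)
    volumes, mask, phenotype, truth = generate_cohort(config)
    mask.save(out / "mask.nii.gz")
    import nibabel as nib
    nib.save(nib.Nifti1Image(truth.astype(np.int16), mask.affine),
             str(out / "ground_truth.nii.gz"))
    ss = np.random.SeedSequence([config.seed, 7])
    trace_seeds = ss.generate_state(len(volumes))
    for i, vol in enumerate(volumes):
        vol.save(out / "bold" / f"{vol.subject_id}_bold.nii.gz")
        trace = generate_motion_trace(config.n_timepoints, motion_max_mm,
                                      motion_max_deg, int(trace_seeds[i]))
        tpath = out / "motion" / f"{vol.subject_id}_motion.txt"
        trace.save(tpath)
        phenotype.loc[i, "motion_trace_path"] = str(tpath)
    phenotype.to_csv(out / "phenotype.csv", index=False)
    return phenotype
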