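"""End-to-end orchestration: simulate -> QC -> ReHo -> classify -> stats.

A single PipelineConfig (YAML-loadable) carries every stage's parameters;
the defaults are the conventional analysis settings (27-voxel cluster, 4 mm
FWHM smoothing, detrending on, C = 1, 1000 permutations, 30% weight-map
threshold, +/-1.5 mm / +/-1.5 deg motion limits). Given the same config and
seed the results JSON is identical run to run.
"""

from __future__ import annotations

import json
import logging
import platform
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .synthetic import SyntheticConfig, write_cohort
from .reho import Volume4D, GreyMask, ReHoMap, MotionTrace, compute_reho_map, \
    smooth_gaussian, qc_motion
from .mvpa import (
    CohortDataset, extract_features, linear_kernel, leave_one_pair_out_cv,
    permutation_test, consensus_weight_map, dual_to_weight_map, train_svm,
    threshold_weight_map, roc_from_margins, FeatureMatrix,
)
from .cohort_stats import (
    two_sample_t, chi_square_2x2, margin_symptom_correlation, LSAS_SCORES,
)

logger = logging.getLogger(__name__)

__all__ = ["RehoParams", "MvpaParams", "QCParams", "PipelineConfig",
           "run_pipeline", "classify_cohort"]


@dataclass
class RehoParams:
    cluster_size: int = 27
    fwhm_mm: float = 4.0
    detrend: bool = True
    edge_policy: str = "intersect"
    masked_smoothing: bool = True


@dataclass
class MvpaParams:
    cost: float = 1.0
    n_permutations: int = 1000
    threshold_fraction: float = 0.30
    normalize: str = "none"  # "none" | "l2" (per-subject feature vector)
    weight_map: str = "fold_average"  # "fold_average" | "full"


@dataclass
class QCParams:
    translation_limit_mm: float = 1.5
    rotation_limit_deg: float = 1.5


@dataclass
class PipelineConfig:
    out_dir: str = "reho_mvpa_out"
    seed: int = 17
    synthetic: SyntheticConfig | None = None
    bold_dir: str | None = None
    mask_path: str | None = None
    phenotype_path: str | None = None
    reho: RehoParams = field(default_factory=RehoParams)
    mvpa: MvpaParams = field(default_factory=MvpaParams)
    qc: QCParams = field(default_factory=QCParams)
    stats_subsets: tuple[str, ...] = ("patients", "all")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        kwargs = {}
        if "synthetic" in raw and raw["synthetic"] is not None:
            kwargs["synthetic"] = SyntheticConfig.from_dict(raw.pop("synthetic"))
        for key, klass in (("reho", RehoParams), ("mvpa", MvpaParams), ("qc", QCParams)):
            if key in raw and raw[key] is not None:
                kwargs[key] = klass(**raw.pop(key))
            else:
                raw.pop(key, None)
        if "stats_subsets" in raw:
            kwargs["stats_subsets"] = tuple(raw.pop("stats_subsets"))
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.synthetic is not None:
            d["synthetic"] = self.synthetic.to_dict()
        return d


def _package_version() -> str:
    from importlib.metadata import version, PackageNotFoundError
    try:
        return version("reho-mvpa")
    except PackageNotFoundError:
        return "unknown"


def _setup_logging(out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("reho_mvpa")
    root.setLevel(logging.INFO)
    root.addHandler(handler)


def simulate_stage(config: PipelineConfig, data_dir: Path) -> None:
    if config.synthetic is None:
        raise ValueError("pipeline stage 'simulate': no synthetic section in config")
    # the pipeline seed overrides the synthetic sub-seed for whole-run reproducibility
    config.synthetic.seed = config.seed
    write_cohort(config.synthetic, data_dir)


def qc_stage(phenotype: pd.DataFrame, qc: QCParams) -> pd.DataFrame:
    rows = []
    for _, rec in phenotype.iterrows():
        path = rec.get("motion_trace_path", "")
        if not path or not Path(str(path)).exists():
            rows.append({"subject_id": rec["subject_id"], "qc": "no-trace",
                         "offending": ""})
            continue
        report = qc_motion(MotionTrace.load(path), qc.translation_limit_mm,
                           qc.rotation_limit_deg)
        rows.append({
            "subject_id": rec["subject_id"],
            "qc": "pass" if report.passed else "fail",
            "offending": ";".join(f"{c}={v:.3f}" for c, v in report.offending),
        })
    return pd.DataFrame(rows)


def reho_stage(volumes: list[Volume4D], mask: GreyMask, params: RehoParams) -> list[ReHoMap]:
    maps = []
    for vol in volumes:
        m = compute_reho_map(vol, mask, cluster_size=params.cluster_size,
                             detrend=params.detrend, edge_policy=params.edge_policy)
        if params.fwhm_mm > 0:
            m = smooth_gaussian(m, params.fwhm_mm, masked=params.masked_smoothing)
        maps.append(m)
    return maps


def classify_cohort(dataset: CohortDataset, params: MvpaParams, seed: int):
    """CV + permutation + weight map + threshold table + ROC on one cohort."""
    features = extract_features(dataset)
    if params.normalize == "l2":
        norms = np.linalg.norm(features.X, axis=1, keepdims=True)
        norms[norms == 0] = 1.0
        features = FeatureMatrix(X=features.X / norms, index_map=features.index_map,
                                 shape=features.shape, n_dropped=features.n_dropped)
    elif params.normalize != "none":
        raise ValueError(f"normalize must be 'none' or 'l2', got {params.normalize!r}")
    kernel = linear_kernel(features)
    cv = leave_one_pair_out_cv(dataset, cost=params.cost, features=features,
                               kernel=kernel)
    perm = permutation_test(dataset, n_permutations=params.n_permutations,
                            seed=seed, cost=params.cost, features=features,
                            kernel=kernel, observed=cv)
    if params.weight_map == "full":
        model = train_svm(kernel, dataset.labels, cost=params.cost)
        wmap = dual_to_weight_map(model, features, dataset.mask)
    else:
        wmap = consensus_weight_map(cv.fold_models, features, dataset.mask)
    wmap.threshold_fraction = params.threshold_fraction
    table = threshold_weight_map(wmap, fraction=params.threshold_fraction)
    roc = roc_from_margins(cv)
    return cv, perm, wmap, table, roc, features


def stats_stage(phenotype: pd.DataFrame, cv_per_subject: pd.DataFrame,
                subsets=("patients", "all")) -> dict:
    pat = phenotype[phenotype["group"] == "patient"]
    con = phenotype[phenotype["group"] == "control"]
    out: dict = {"demographics": {}, "margin_correlations": []}
    t_age = two_sample_t(pat["age"].to_numpy(), con["age"].to_numpy())
    out["demographics"]["age"] = {"t": t_age.t, "df": t_age.df, "p": t_age.p}
    for score in LSAS_SCORES:
        if score in phenotype.columns:
            r = two_sample_t(pat[score].to_numpy(), con[score].to_numpy())
            out["demographics"][score] = {"t": r.t, "df": r.df, "p": r.p}
    sex_table = [
        [int((pat["sex"] == "F").sum()), int((pat["sex"] == "M").sum())],
        [int((con["sex"] == "F").sum()), int((con["sex"] == "M").sum())],
    ]
    try:
        chi = chi_square_2x2(sex_table)
        out["demographics"]["sex"] = {"chi2": chi.chi2, "df": chi.df, "p": chi.p,
                                      "table": sex_table}
    except ValueError as exc:
        out["demographics"]["sex"] = {"error": str(exc), "table": sex_table}
    for subset in subsets:
        for score in LSAS_SCORES:
            if score not in phenotype.columns:
                continue
            for method in ("pearson", "spearman"):
                c = margin_symptom_correlation(cv_per_subject, phenotype,
                                               score=score, subset=subset,
                                               method=method)
                out["margin_correlations"].append(asdict(c))
    return out


def run_pipeline(config: PipelineConfig) -> dict:
    """Run every stage in order and write all artifacts under out_dir.

    Returns the machine-readable run report (also written as report.json):
    config echo, package/library versions, per-stage timings, and the
    headline statistics. Deterministic given (config, seed), timings aside.
    """
    out = Path(config.out_dir)
    _setup_logging(out)
    timings: dict[str, float] = {}
    report: dict = {
        "config": config.to_dict(),
        "versions": {"reho_mvpa": _package_version(), "python": platform.python_version(),
                     "numpy": np.__version__},
        "seed": config.seed,
    }

    t0 = time.perf_counter()
    if config.synthetic is not None:
        data_dir = out / "data"
        simulate_stage(config, data_dir)
        bold_dir = data_dir / "bold"
        mask_path = data_dir / "mask.nii.gz"
        phenotype_path = data_dir / "phenotype.csv"
    else:
        if not (config.bold_dir and config.mask_path and config.phenotype_path):
            raise ValueError("pipeline: need either a synthetic section or "
                             "bold_dir + mask_path + phenotype_path")
        bold_dir = Path(config.bold_dir)
        mask_path = Path(config.mask_path)
        phenotype_path = Path(config.phenotype_path)
    for path in (bold_dir, mask_path, phenotype_path):
        if not Path(path).exists():
            raise FileNotFoundError(f"pipeline stage 'load': missing input {path}")
    timings["simulate"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    phenotype = pd.read_csv(phenotype_path)
    mask = GreyMask.load(mask_path)
    qc_table = qc_stage(phenotype, config.qc)
    qc_table.to_csv(out / "qc.csv", index=False)
    failed = set(qc_table.loc[qc_table["qc"] == "fail", "subject_id"])
    if failed:
        logger.warning("QC failed for %s; excluding them and their pair mates "
                       "to keep groups balanced", sorted(failed))
        pat = phenotype[phenotype["group"] == "patient"].reset_index(drop=True)
        con = phenotype[phenotype["group"] == "control"].reset_index(drop=True)
        drop_pairs = [k for k in range(min(len(pat), len(con)))
                      if pat.loc[k, "subject_id"] in failed
                      or con.loc[k, "subject_id"] in failed]
        keep = pd.concat([pat.drop(index=drop_pairs), con.drop(index=drop_pairs)])
        phenotype = keep.reset_index(drop=True)
    timings["qc"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    volumes = []
    for sid in phenotype["subject_id"]:
        path = Path(bold_dir) / f"{sid}_bold.nii.gz"
        if not path.exists():
            path = Path(bold_dir) / f"{sid}_bold.nii"
        if not path.exists():
            raise FileNotFoundError(f"pipeline stage 'reho': missing volume {path}")
        volumes.append(Volume4D.load(path, subject_id=sid))
    maps = reho_stage(volumes, mask, config.reho)
    reho_dir = out / "reho"
    reho_dir.mkdir(exist_ok=True)
    for m in maps:
        m.save(reho_dir / f"{m.subject_id}_reho.nii.gz")
    timings["reho"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    dataset = CohortDataset.from_phenotype(
        phenotype, {m.subject_id: m for m in maps}, mask)
    cv, perm, wmap, table, roc, _features = classify_cohort(
        dataset, config.mvpa, seed=config.seed)
    _save_weight_map(wmap, out / "weight_map.nii.gz")
    table.to_csv(out / "discrimination_table.tsv", sep="\t", index=False)
    pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
        out / "roc_points.tsv", sep="\t", index=False)
    cv.per_subject.to_csv(out / "per_subject.csv", index=False)
    results = {
        "accuracy": cv.accuracy,
        "sensitivity": cv.sensitivity,
        "specificity": cv.specificity,
        "p_values": perm.p_values,
        "n_permutations": perm.n_permutations,
        "auc": roc.auc,
        "per_subject_margins": dict(zip(cv.per_subject["subject_id"],
                                        cv.per_subject["test_margin"])),
    }
    with open(out / "results.json", "w") as fh:
        json.dump(results, fh, indent=2)
    timings["classify"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    stats = stats_stage(phenotype, cv.per_subject, subsets=config.stats_subsets)
    with open(out / "stats.json", "w") as fh:
        json.dump(stats, fh, indent=2)
    timings["stats"] = time.perf_counter() - t0

    report["timings_s"] = timings
    report["results"] = results
    report["stats"] = stats
    report["artifacts"] = {
        "weight_map": str(out / "weight_map.nii.gz"),
        "discrimination_table": str(out / "discrimination_table.tsv"),
        "roc_points": str(out / "roc_points.tsv"),
        "results": str(out / "results.json"),
        "stats": str(out / "stats.json"),
        "qc": str(out / "qc.csv"),
    }
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report


def _save_weight_map(wmap, path) -> None:
    import nibabel as nib
    img = nib.Nifti1Image(wmap.data.astype(np.float32), wmap.mask.affine)
    nib.save(img, str(path))
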