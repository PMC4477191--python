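"""Linear-SVM multivariate pattern analysis of ReHo maps.

Subjects' in-mask ReHo values form the feature vectors x_i with diagnostic
labels c_i in {+1 patient, -1 control}. A soft-margin linear SVM (fixed
C = 1 by convention) is trained on the precomputed Gram matrix K_ij =
x_i . x_j. Generalization is estimated by leave-one-pair-out
cross-validation: each fold holds out one patient and one matched control,
trains on the remainder, and predicts both. Significance of the observed
accuracy/sensitivity/specificity is assessed by balanced permutation of the
group labels with the entire cross-validation re-run per permutation. The
primal weight vector w = sum_i alpha_i c_i x_i is scattered back into brain
space as the discrimination map; voxels with |w| at or above a fraction
(default 30%) of max|w| are reported as clusters. Each held-out subject's
signed test margin (w . x + b) / ||w|| feeds the ROC analysis and the
margin-symptom correlations.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.svm import SVC
from sklearn.metrics import roc_curve, auc as _auc

from .reho import GreyMask, ReHoMap

logger = logging.getLogger(__name__)

__all__ = [
    "CohortDataset",
    "FeatureMatrix",
    "SvmModel",
    "CVResult",
    "WeightMap",
    "PermutationResult",
    "ROCCurve",
    "extract_features",
    "linear_kernel",
    "train_svm",
    "decision_values",
    "dual_to_weight_map",
    "leave_one_pair_out_cv",
    "permutation_test",
    "consensus_weight_map",
    "threshold_weight_map",
    "roc_from_margins",
]


@dataclass
class CohortDataset:
    """ReHo maps with diagnostic labels: the MVPA input."""

    subject_ids: list[str]
    maps: list[ReHoMap]
    labels: np.ndarray  # +1 patient, -1 control
    mask: GreyMask
    phenotype: pd.DataFrame | None = None

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if not (len(self.subject_ids) == len(self.maps) == len(self.labels)):
            raise ValueError("subject_ids, maps and labels must have equal length")
        if not set(np.unique(self.labels)) <= {-1, 1}:
            raise ValueError("labels must be +1 (patient) or -1 (control)")
        if len(set(np.unique(self.labels))) < 2:
            raise ValueError("both labels must be present")
        shapes = {m.data.shape for m in self.maps}
        if len(shapes) > 1:
            raise ValueError(f"maps have inconsistent shapes: {shapes}")
        if self.maps and self.maps[0].data.shape != self.mask.data.shape:
            raise ValueError("maps and mask shapes disagree")

    @property
    def n_subjects(self) -> int:
        return len(self.maps)

    @classmethod
    def from_phenotype(cls, phenotype: pd.DataFrame, maps_by_id: dict[str, ReHoMap],
                       mask: GreyMask, patient_label: str = "patient") -> "CohortDataset":
        ids = list(phenotype["subject_id"])
        labels = np.where(phenotype["group"].astype(str) == patient_label, 1, -1)
        return cls(subject_ids=ids, maps=[maps_by_id[i] for i in ids],
                   labels=labels, mask=mask, phenotype=phenotype)


@dataclass
class FeatureMatrix:
    """Subjects-by-voxels feature matrix plus the flat voxel indices that
    recover each column's 3D location."""

    X: np.ndarray
    index_map: np.ndarray  # flat indices into the mask grid, one per column
    shape: tuple[int, int, int]
    n_dropped: int = 0

    def scatter(self, vector: np.ndarray) -> np.ndarray:
        """Place a per-column vector back into a 3D grid, zeros off-mask."""
        vector = np.asarray(vector, dtype=np.float64)
        if vector.shape != (self.X.shape[1],):
            raise ValueError(
                f"vector length {vector.shape} does not match {self.X.shape[1]} features"
            )
        out = np.zeros(int(np.prod(self.shape)))
        out[self.index_map] = vector
        return out.reshape(self.shape)


def extract_features(dataset: CohortDataset) -> FeatureMatrix:
    """Stack the cohort's in-mask ReHo values into (subjects x voxels).

    Voxels that are no-data for any subject are dropped cohort-wide so all
    rows share one column space; drops are logged. Row order follows the
    dataset's subject order; column order is the C-order linearization of
    the surviving in-mask voxel indices.
    """
    m = dataset.mask.data
    stacked = np.stack([mp.data for mp in dataset.maps])  # (n_sub, x, y, z)
    finite_all = np.all(np.isfinite(stacked), axis=0) & m
    n_dropped = int(m.sum() - finite_all.sum())
    if n_dropped:
        logger.info("extract_features: dropped %d of %d in-mask voxels lacking "
                    "data for at least one subject", n_dropped, int(m.sum()))
    index_map = np.flatnonzero(finite_all.ravel())
    X = stacked.reshape(dataset.n_subjects, -1)[:, index_map]
    return FeatureMatrix(X=X, index_map=index_map, shape=m.shape, n_dropped=n_dropped)


def linear_kernel(features: FeatureMatrix | np.ndarray) -> np.ndarray:
    """Gram matrix of dot products K_ij = x_i . x_j."""
    X = features.X if isinstance(features, FeatureMatrix) else np.asarray(features)
    bad = np.flatnonzero(~np.all(np.isfinite(X), axis=1))
    if bad.size:
        raise ValueError(f"non-finite features for subject rows {bad.tolist()}")
    K = X @ X.T
    return (K + K.T) / 2.0  # enforce exact symmetry


@dataclass
class SvmModel:
    """Dual-form soft-margin linear SVM solution.

    dual_coefficients[i] = alpha_i * c_i for every training subject (zero
    for non-support vectors); the decision value of a test point with kernel
    row k is k . dual_coefficients + bias.
    """

    dual_coefficients: np.ndarray
    bias: float
    support_indices: np.ndarray
    cost: float
    training_indices: np.ndarray  # positions in the cohort kernel
    training_ids: list[str] = field(default_factory=list)

    @property
    def support_ids(self) -> list[str]:
        if not self.training_ids:
            return []
        return [self.training_ids[i] for i in self.support_indices]

    def weight_norm(self, K_train: np.ndarray) -> float:
        """||w|| from the kernel: w.w = a^T K a with a the dual coefficients."""
        a = self.dual_coefficients
        return float(np.sqrt(max(a @ K_train @ a, 0.0)))


def train_svm(kernel: np.ndarray, labels: np.ndarray, cost: float = 1.0,
              training_ids: list[str] | None = None,
              tol: float = 1e-9) -> SvmModel:
    """Train a soft-margin SVM on a precomputed linear kernel.

    C (``cost``) fixes the trade-off between margin width and training
    errors; the conventional default is 1. The solver tolerance is kept
    tight so KKT conditions hold to ~1e-6.
    """
    kernel = np.asarray(kernel, dtype=np.float64)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if classes.size < 2:
        raise ValueError("train_svm requires both classes in the labels")
    clf = SVC(kernel="precomputed", C=cost, tol=tol)
    clf.fit(kernel, labels)
    dual = np.zeros(kernel.shape[0])
    dual[clf.support_] = clf.dual_coef_[0]
    return SvmModel(
        dual_coefficients=dual,
        bias=float(clf.intercept_[0]),
        support_indices=clf.support_.copy(),
        cost=cost,
        training_indices=np.arange(kernel.shape[0]),
        training_ids=list(training_ids) if training_ids else [],
    )


def decision_values(model: SvmModel, kernel_rows: np.ndarray) -> np.ndarray:
    """Decision values f(x) = sum_i a_i K(x_i, x) + b for rows of the kernel
    against the model's training subjects."""
    kernel_rows = np.atleast_2d(np.asarray(kernel_rows, dtype=np.float64))
    return kernel_rows @ model.dual_coefficients + model.bias


@dataclass
class WeightMap:
    """Signed 3D discrimination map; positive = higher weight for the
    patient class."""

    data: np.ndarray
    mask: GreyMask
    threshold_fraction: float = 0.30


def dual_to_weight_map(model: SvmModel, features: FeatureMatrix,
                       mask: GreyMask) -> WeightMap:
    """Reconstruct w = sum_i alpha_i c_i x_i and scatter it into brain space.

    `features` must be the matrix the model was trained on (same row order).
    """
    if features.X.shape[0] != model.dual_coefficients.shape[0]:
        raise ValueError(
            f"model trained on {model.dual_coefficients.shape[0]} subjects but "
            f"features have {features.X.shape[0]} rows"
        )
    w = model.dual_coefficients @ features.X
    return WeightMap(data=features.scatter(w), mask=mask)


@dataclass
class CVResult:
    """Held-out predictions from leave-one-pair-out cross-validation."""

    per_subject: pd.DataFrame  # subject_id, true_label, predicted_label, test_margin
    accuracy: float
    sensitivity: float
    specificity: float
    fold_models: list[SvmModel] = field(default_factory=list)


def _pairs_from_labels(labels: np.ndarray,
                       pair_ids: np.ndarray | None = None) -> list[tuple[int, int]]:
    """Patient/control index pairs: k-th patient with k-th control in subject
    order, or matched by an explicit pair_id column."""
    pat = np.flatnonzero(labels == 1)
    con = np.flatnonzero(labels == -1)
    if pat.size != con.size:
        raise ValueError(
            f"leave-one-pair-out requires equal group sizes, got {pat.size} "
            f"patients and {con.size} controls; trim or use an unbalanced scheme"
        )
    if pair_ids is not None:
        con_by_pid = {pair_ids[j]: j for j in con}
        if len(con_by_pid) != con.size:
            raise ValueError("pair_id values must be unique within each group")
        try:
            return [(int(i), int(con_by_pid[pair_ids[i]])) for i in pat]
        except KeyError as exc:
            raise ValueError(f"pair_id {exc.args[0]!r} has no control match") from None
    return list(zip(pat.tolist(), con.tolist()))


def _lopo_cv_kernel(K: np.ndarray, labels: np.ndarray, cost: float,
                    pairs: list[tuple[int, int]],
                    keep_models: bool = False,
                    tol: float = 1e-9):
    """Core leave-one-pair-out loop on a precomputed cohort kernel."""
    n = K.shape[0]
    preds = np.zeros(n, dtype=np.int64)
    margins = np.zeros(n)
    models: list[SvmModel] = []
    for i_pat, i_con in pairs:
        test = [i_pat, i_con]
        train = np.setdiff1d(np.arange(n), test)
        model = train_svm(K[np.ix_(train, train)], labels[train], cost=cost, tol=tol)
        model.training_indices = train
        wnorm = model.weight_norm(K[np.ix_(train, train)])
        f = decision_values(model, K[np.ix_(test, train)])
        for j, fj in zip(test, f):
            # decision value exactly 0 predicts control (deterministic tie-break)
            if fj == 0.0:
                logger.info("decision value exactly 0 for subject index %d; "
                            "predicting control", j)
            preds[j] = 1 if fj > 0 else -1
            margins[j] = fj / wnorm if wnorm > 0 else 0.0
        if keep_models:
            models.append(model)
    is_pat = labels == 1
    sens = float(np.mean(preds[is_pat] == 1))
    spec = float(np.mean(preds[~is_pat] == -1))
    acc = float(np.mean(preds == labels))
    return preds, margins, acc, sens, spec, models


def leave_one_pair_out_cv(dataset: CohortDataset, cost: float = 1.0,
                          features: FeatureMatrix | None = None,
                          kernel: np.ndarray | None = None,
                          keep_models: bool = True) -> CVResult:
    """Leave-one-pair-out cross-validation of the linear SVM.

    Each fold excludes one patient and one control (paired by phenotype-file
    order, or by a `pair_id` phenotype column when present), trains on the
    remaining subjects, and predicts the held-out pair. The signed test
    margin (w . x + b) / ||w|| is recorded per subject; positive lies on the
    patient side of the hyperplane.
    """
    if features is None:
        features = extract_features(dataset)
    if kernel is None:
        kernel = linear_kernel(features)
    pair_ids = None
    if dataset.phenotype is not None and "pair_id" in dataset.phenotype.columns:
        pair_ids = dataset.phenotype["pair_id"].to_numpy()
    pairs = _pairs_from_labels(dataset.labels, pair_ids)
    preds, margins, acc, sens, spec, models = _lopo_cv_kernel(
        kernel, dataset.labels, cost, pairs, keep_models=keep_models
    )
    per_subject = pd.DataFrame({
        "subject_id": dataset.subject_ids,
        "true_label": dataset.labels,
        "predicted_label": preds,
        "test_margin": margins,
    })
    return CVResult(per_subject=per_subject, accuracy=acc, sensitivity=sens,
                    specificity=spec, fold_models=models)


@dataclass
class PermutationResult:
    n_permutations: int
    observed: dict[str, float]
    null_statistics: pd.DataFrame  # columns accuracy, sensitivity, specificity
    p_values: dict[str, float]


def permutation_test(dataset: CohortDataset, n_permutations: int = 1000,
                     seed: int = 0, cost: float = 1.0,
                     features: FeatureMatrix | None = None,
                     kernel: np.ndarray | None = None,
                     observed: CVResult | None = None) -> PermutationResult:
    """Permutation test of the cross-validated classification.

    Group labels are randomly permuted over subjects (balanced: group sizes
    preserved), the pairing is re-derived on the permuted labels, and the
    full leave-one-pair-out CV is re-run; this repeats `n_permutations`
    times. p = (1 + #{null >= observed}) / (n_permutations + 1) for each of
    accuracy, sensitivity and specificity, plus a joint `both_exceed` rule
    counting permutations where null sensitivity and specificity are both at
    least the observed values.
    """
    if n_permutations < 1:
        raise ValueError(f"n_permutations must be >= 1, got {n_permutations}")
    if features is None:
        features = extract_features(dataset)
    if kernel is None:
        kernel = linear_kernel(features)
    if observed is None:
        observed = leave_one_pair_out_cv(dataset, cost=cost, features=features,
                                         kernel=kernel, keep_models=False)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(n_permutations):
        perm_labels = rng.permutation(dataset.labels)
        pairs = _pairs_from_labels(perm_labels)
        _, _, acc, sens, spec, _ = _lopo_cv_kernel(kernel, perm_labels, cost, pairs)
        rows.append((acc, sens, spec))
    null = pd.DataFrame(rows, columns=["accuracy", "sensitivity", "specificity"])
    obs = {"accuracy": observed.accuracy, "sensitivity": observed.sensitivity,
           "specificity": observed.specificity}
    m = n_permutations
    p_values = {
        stat: float((1 + int((null[stat] >= obs[stat]).sum())) / (m + 1))
        for stat in obs
    }
    joint = (null["sensitivity"] >= obs["sensitivity"]) & \
            (null["specificity"] >= obs["specificity"])
    p_values["both_exceed"] = float((1 + int(joint.sum())) / (m + 1))
    return PermutationResult(n_permutations=m, observed=obs,
                             null_statistics=null, p_values=p_values)


def consensus_weight_map(fold_models: list[SvmModel], features: FeatureMatrix,
                         mask: GreyMask) -> WeightMap:
    """Average discrimination map across CV folds.

    Each fold's weight vector is reconstructed from its training subjects,
    normalized to unit length, and the fold-mean is scattered into brain
    space. (The single-model alternative is `dual_to_weight_map` on a model
    trained on the full cohort.)
    """
    if not fold_models:
        raise ValueError("consensus_weight_map needs at least one fold model")
    acc = np.zeros(features.X.shape[1])
    for model in fold_models:
        w = model.dual_coefficients @ features.X[model.training_indices]
        norm = np.linalg.norm(w)
        acc += w / norm if norm > 0 else w
    return WeightMap(data=features.scatter(acc / len(fold_models)), mask=mask)


def threshold_weight_map(weight_map: WeightMap, fraction: float = 0.30) -> pd.DataFrame:
    """Threshold the discrimination map at a fraction of max|w| and report
    surviving clusters.

    Voxels with |w| >= fraction * max|w| are retained (inclusive), grouped
    by 26-connectivity, and summarized by their peak-|w| voxel: index,
    millimetre coordinates via the mask affine, signed peak weight, and the
    sign interpretation (positive identifies patients).
    """
    if not (0 < fraction <= 1):
        raise ValueError(f"fraction must lie in (0, 1], got {fraction}")
    w = weight_map.data
    wmax = float(np.nanmax(np.abs(w)))
    columns = ["cluster", "n_voxels", "peak_i", "peak_j", "peak_k",
               "peak_x_mm", "peak_y_mm", "peak_z_mm", "peak_weight", "class"]
    if wmax == 0:
        warnings.warn("all-zero weight map: empty discrimination table")
        return pd.DataFrame(columns=columns)
    survive = np.abs(w) >= fraction * wmax
    labeled, n_clusters = ndimage.label(survive, structure=np.ones((3, 3, 3)))
    affine = weight_map.mask.affine
    rows = []
    for c in range(1, n_clusters + 1):
        idx = np.argwhere(labeled == c)
        vals = w[tuple(idx.T)]
        peak = idx[np.argmax(np.abs(vals))]
        peak_w = float(w[tuple(peak)])
        mm = affine @ np.append(peak, 1.0)
        rows.append({
            "cluster": c, "n_voxels": len(idx),
            "peak_i": int(peak[0]), "peak_j": int(peak[1]), "peak_k": int(peak[2]),
            "peak_x_mm": float(mm[0]), "peak_y_mm": float(mm[1]), "peak_z_mm": float(mm[2]),
            "peak_weight": peak_w,
            "class": "patient" if peak_w > 0 else "control",
        })
    table = pd.DataFrame(rows, columns=columns)
    return table.sort_values("peak_weight", ascending=False,
                             key=np.abs).reset_index(drop=True)


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float


def roc_from_margins(cv: CVResult) -> ROCCurve:
    """ROC curve over test-margin thresholds, with trapezoidal AUC.

    Margins score the patient class (+1); all-identical margins yield a
    degenerate chance-level curve (AUC 0.5) with a warning.
    """
    y = cv.per_subject["true_label"].to_numpy()
    margins = cv.per_subject["test_margin"].to_numpy()
    if not np.all(np.isfinite(margins)):
        raise ValueError("non-finite test margins")
    if np.all(margins == margins[0]):
        warnings.warn("all test margins identical: degenerate ROC, AUC = 0.5")
        return ROCCurve(fpr=np.array([0.0, 1.0]), tpr=np.array([0.0, 1.0]),
                        thresholds=np.array([np.inf, margins[0]]), auc=0.5)
    fpr, tpr, thr = roc_curve(y, margins, pos_label=1)
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(_auc(fpr, tpr)))
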