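import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, deadline=None)
settings.load_profile("ci")
from scipy.optimize import minimize, LinearConstraint
from scipy.stats import rankdata

import reho_mvpa as rm
from reho_mvpa.reho import cluster_offsets


def brute_force_kendalls_w(block):
    """Independent rank-sum implementation of Kendall's W (midranks,
    tie-uncorrected denominator), written as the direct formula."""
    block = np.asarray(block, dtype=float)
    k, n = block.shape
    ranks = np.array([rankdata(row) for row in block])
    r = ranks.sum(axis=0)
    rbar = k * (n + 1) / 2
    s = np.sum((r - rbar) ** 2)
    return 12.0 * s / (k * k * (n ** 3 - n))


def brute_force_reho(volume, mask, cluster_size=27, detrend=True,
                     edge_policy="intersect"):
    """Naive per-voxel loop oracle for the ReHo map."""
    from scipy.signal import detrend as sp_detrend

    data = volume.data
    if detrend:
        data = sp_detrend(data, axis=-1, type="linear")
    m = mask.data
    shape = m.shape
    offsets = cluster_offsets(cluster_size)
    out = np.full(shape, np.nan)
    for x in range(shape[0]):
        for y in range(shape[1]):
            for z in range(shape[2]):
                if not m[x, y, z]:
                    continue
                block = []
                for dx, dy, dz in offsets:
                    i, j, k = x + dx, y + dy, z + dz
                    if 0 <= i < shape[0] and 0 <= j < shape[1] and 0 <= k < shape[2] \
                            and m[i, j, k]:
                        block.append(data[i, j, k])
                if edge_policy == "full" and len(block) != cluster_size:
                    continue
                if len(block) < 2:
                    continue
                out[x, y, z] = brute_force_kendalls_w(np.array(block))
    return out


def primal_svm_decisions(X, y, C=1.0):
    """Independent soft-margin SVM oracle: solve the primal hinge-loss QP
    (representer-parametrized, w = X^T beta) with scipy trust-constr and
    return training decision values."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n = X.shape[0]
    K = X @ X.T

    def obj(z):
        beta, xi = z[:n], z[n + 1:]
        return 0.5 * beta @ K @ beta + C * xi.sum()

    def jac(z):
        g = np.empty(2 * n + 1)
        g[:n] = K @ z[:n]
        g[n] = 0.0
        g[n + 1:] = C
        return g

    A = np.hstack([y[:, None] * K, y[:, None], np.eye(n)])
    con = LinearConstraint(A, lb=1.0, ub=np.inf)
    bounds = [(-np.inf, np.inf)] * (n + 1) + [(0.0, np.inf)] * n
    z0 = np.zeros(2 * n + 1)
    z0[n + 1:] = 1.0
    res = minimize(obj, z0, jac=jac, method="trust-constr", bounds=bounds,
                   constraints=[con],
                   options={"maxiter": 20000, "gtol": 1e-14, "xtol": 1e-16,
                            "barrier_tol": 1e-14})
    beta, b = res.x[:n], res.x[n]
    return K @ beta + b


def make_dataset(config, fwhm_mm=0.0):
    """Generate a cohort and turn it into a CohortDataset of ReHo maps."""
    vols, mask, pheno, truth = rm.generate_cohort(config)
    maps = []
    for v in vols:
        m = rm.compute_reho_map(v, mask)
        if fwhm_mm > 0:
            m = rm.smooth_gaussian(m, fwhm_mm)
        maps.append(m)
    ds = rm.CohortDataset.from_phenotype(pheno, {m.subject_id: m for m in maps},
                                         mask)
    return ds, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_null_config():
    return rm.SyntheticConfig(grid_shape=(8, 8, 8), n_timepoints=60,
                              n_per_group=10, seed=7)


@pytest.fixture(scope="session")
def strong_effect_config():
    return rm.SyntheticConfig(
        grid_shape=(10, 10, 10), n_timepoints=200, n_per_group=10,
        effect_regions=[rm.EffectRegion(box=((3, 8), (3, 8), (3, 8)),
                                        rho_group0=0.0, rho_group1=0.8)],
        seed=3,
    )
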