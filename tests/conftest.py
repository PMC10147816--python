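"""Shared fixtures and independent oracles for the test suite."""

from __future__ import annotations

from functools import lru_cache

import numpy as np
import pytest

import dogconn as dc


# ---------------------------------------------------------------------------
# independent oracles


def brute_semipartial(X: np.ndarray) -> np.ndarray:
    """Explicit per-pair OLS residualization (no intercept, as the contract
    assumes standardized columns), the slow reference for the
    precision-downdate implementation."""
    X = np.asarray(X, float)
    p = X.shape[1]
    s = np.zeros((p, p))
    for i in range(p):
        for j in range(p):
            if i == j:
                continue
            others = [k for k in range(p) if k not in (i, j)]
            if others:
                Z = X[:, others]
                beta, *_ = np.linalg.lstsq(Z, X[:, i], rcond=None)
                resid = X[:, i] - Z @ beta
            else:
                resid = X[:, i]
            denom = np.linalg.norm(X[:, j]) * np.linalg.norm(resid)
            s[i, j] = X[:, j] @ resid / denom
    r = (s + s.T) / 2.0
    np.fill_diagonal(r, 0.0)
    return r


def brute_bh_stepup(p: list[float]) -> list[float]:
    """Step-up BH by direct definition: q_(i) = min over j>=i of m*p_(j)/j."""
    m = len(p)
    order = np.argsort(p)
    q_sorted = [min(m * p[order[j]] / (j + 1) for j in range(i, m)) for i in range(m)]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q.tolist()


def spearman_oracle(x, y) -> float:
    """Rank both sides, then Pearson on the ranks (average ranks for ties)."""
    from scipy.stats import rankdata

    rx, ry = rankdata(x), rankdata(y)
    return float(np.corrcoef(rx, ry)[0, 1])


# ---------------------------------------------------------------------------
# cohorts


@lru_cache(maxsize=12)
def run_default_cohort(seed: int, n_perm: int = 1000):
    """Full default-cohort pipeline run, cached across tests.

    Returns (metadata, generator spec, analysis result). Small-world scalars
    are skipped here; tests that need them call small_world directly.
    """
    meta = dc.default_metadata(seed=seed)
    spec = dc.default_generator_spec(meta, seed=seed)
    cohort = dc.generate_timeseries(meta, spec)
    cfg = dc.PipelineConfig(seed=seed, n_perm=n_perm)
    res = dc.analyze_cohort(cohort, meta, cfg, compute_small_world=False)
    return meta, spec, res


def tiny_module_plan():
    """22-ROI plan with one lateralized twin pair-set (fast end-to-end runs)."""
    return [
        dc.ModuleSpec("alpha", n_pairs=3, n_midline=1),
        dc.ModuleSpec("beta", n_pairs=2, n_midline=1),
        dc.ModuleSpec("tau", n_pairs=5, lateralized=True),
    ]


@pytest.fixture(scope="session")
def tiny_meta():
    return dc.generate_metadata(10, 2, tiny_module_plan(), seed=7)


@pytest.fixture(scope="session")
def default_run():
    return run_default_cohort(1)


@pytest.fixture(scope="session")
def tiny_cohort(tiny_meta):
    """12 subjects x 80 time points on the 22-ROI atlas."""
    spec = dc.default_generator_spec(tiny_meta, n_subjects=12, n_timepoints=80, seed=7)
    return dc.generate_timeseries(tiny_meta, spec), spec
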