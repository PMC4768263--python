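"""Shared fixtures: tiny hand-built screens and planted scenarios."""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import coopharm as cp

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


def make_dataset(alterations: dict[str, list[int]],
                 expression: dict[str, list[float]],
                 responses: dict[str, list[float]],
                 cells: list[str] | None = None,
                 higher_is_sensitive: bool = True,
                 name: str = "toy") -> cp.PharmacogenomicDataset:
    """Build an aligned dataset from plain dicts (row key -> per-cell values)."""
    n = len(next(iter(alterations.values())))
    cells = cells or [f"C{i}" for i in range(n)]
    metric = cp.SensitivityMetric(
        "activity_area" if higher_is_sensitive else "ln_IC50",
        higher_is_sensitive)
    return cp.PharmacogenomicDataset(
        alterations=pd.DataFrame(alterations, index=cells).T,
        expression=pd.DataFrame(expression, index=cells).T.astype(float),
        responses=pd.DataFrame(responses, index=cells).T.astype(float),
        metric=metric,
        name=name,
    )


def mw_enumeration_p(a, b) -> float:
    """Independent full-enumeration two-sided Mann-Whitney p (tie-free).

    Enumerates every assignment of the pooled values to the two group
    sizes, computes the exact null distribution of U, and returns
    2 * min(P(U <= u_obs), P(U >= u_obs)) capped at 1.
    """
    a, b = list(map(float, a)), list(map(float, b))
    pooled = a + b
    assert len(set(pooled)) == len(pooled), "oracle requires tie-free data"

    def u_stat(group_a, group_b):
        return sum(1 for x in group_a for y in group_b if x > y)

    u_obs = u_stat(a, b)
    us = [u_stat([pooled[i] for i in idx],
                 [pooled[i] for i in range(len(pooled)) if i not in set(idx)])
          for idx in combinations(range(len(pooled)), len(a))]
    total = len(us)
    p_low = sum(u <= u_obs for u in us) / total
    p_high = sum(u >= u_obs for u in us) / total
    return min(1.0, 2.0 * min(p_low, p_high))


def bh_stepup_reference(p) -> np.ndarray:
    """Independent BH step-up: sort, q_i = p_i * m / i, enforce monotone
    non-increasing from the largest rank down, cap at 1, restore order."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = p[order] * m / np.arange(1, m + 1)
    for i in range(m - 2, -1, -1):
        q[i] = min(q[i], q[i + 1])
    q = np.minimum(q, 1.0)
    out = np.empty(m)
    out[order] = q
    return out


@pytest.fixture
def planted_single_driver() -> cp.PharmacogenomicDataset:
    """Noiseless 40-cell screen: G:MUT carriers respond 10.00..10.19,
    wild-type 0.00..0.19 — child medians 10.095 and 0.095."""
    alt = {f"C{i}": [1 if i < 20 else 0] for i in range(40)}
    resp = {f"C{i}": [10.0 + 0.01 * i if i < 20 else 0.01 * (i - 20)]
            for i in range(40)}
    expr = {f"C{i}": [0.0] for i in range(40)}
    cells = [f"C{i}" for i in range(40)]
    return cp.PharmacogenomicDataset(
        alterations=pd.DataFrame(alt, index=["G:MUT"]),
        expression=pd.DataFrame(expr, index=["E1"]).astype(float),
        responses=pd.DataFrame(resp, index=["drugX"]).astype(float),
        metric=cp.SensitivityMetric.activity_area(),
        name="planted",
    )


@pytest.fixture
def two_level_dataset() -> cp.PharmacogenomicDataset:
    """Seeded 60-cell screen with driver G1 and a secondary feature G2 that
    matters only inside G1-mutant cells."""
    rng = np.random.default_rng(42)
    n = 60
    g1 = np.array([1] * 30 + [0] * 30)
    g2 = np.zeros(n, dtype=int)
    g2[:15] = 1          # G2 altered in half the G1-mutants
    g2[30:40] = 1        # ... and in some G1-wildtype cells (no effect there)
    y = 1.0 + 10.0 * g1 - 5.0 * (g1 * g2) + rng.normal(0, 0.1, n)
    cells = [f"C{i}" for i in range(n)]
    return cp.PharmacogenomicDataset(
        alterations=pd.DataFrame(
            np.vstack([g1, g2]), index=["G1:MUT", "G2:MUT"], columns=cells),
        expression=pd.DataFrame(
            rng.normal(0, 1, (2, n)), index=["E1", "E2"], columns=cells),
        responses=pd.DataFrame([y], index=["drugX"], columns=cells),
        metric=cp.SensitivityMetric.activity_area(),
        name="two_level",
    )


def noise_dataset(seed: int, n_cells: int = 30,
                  n_features: int = 100) -> cp.PharmacogenomicDataset:
    """Pure-noise screen: alterations and responses carry no association."""
    rng = np.random.default_rng(seed)
    cells = [f"C{i}" for i in range(n_cells)]
    alt = (rng.random((n_features, n_cells)) < 0.3).astype(int)
    return cp.PharmacogenomicDataset(
        alterations=pd.DataFrame(
            alt, index=[f"F{i:03d}:MUT" for i in range(n_features)],
            columns=cells),
        expression=pd.DataFrame(rng.normal(0, 1, (3, n_cells)),
                                index=["E1", "E2", "E3"], columns=cells),
        responses=pd.DataFrame([rng.normal(0, 1, n_cells)],
                               index=["drugX"], columns=cells),
        metric=cp.SensitivityMetric.activity_area(),
        name="noise",
    )
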