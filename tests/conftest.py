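"""Shared fixtures and independent oracles.

The bootstrap runs used by several test modules are session-scoped (one
run each at B = 100,000) so the suite pays for them once.  The grid-search
fixed-point oracle is written directly from the defining equations,
independently of the package's Jacobi iteration, so it can vouch for the
solver rather than echo it.
"""

from __future__ import annotations

import numpy as np
import pytest
from scipy import optimize

import mfvboot as mb

ACCEPTANCE_SEED = 2025
ACCEPTANCE_B = 100_000


@pytest.fixture(scope="session")
def table1():
    return mb.builtin_dataset("ag108m_xs_original")


@pytest.fixture(scope="session")
def merged():
    return mb.builtin_dataset("ag108m_xs_reevaluated")


@pytest.fixture(scope="session")
def halflife5():
    return mb.builtin_dataset("ag108m_halflife_5")


@pytest.fixture(scope="session")
def halflife3():
    return mb.builtin_dataset("ag108m_halflife_3")


def _hpb(table, seed, B, track=False):
    settings = mb.BootstrapSettings(
        method="hybrid", replicates=B, seed=seed, lower_bound=0.0, track_origins=track
    )
    return mb.hybrid_parametric_bootstrap_mfv(table, settings)


@pytest.fixture(scope="session")
def reeval_hpb(merged):
    """HPB distribution of the re-evaluated cross-section table."""
    return _hpb(merged, ACCEPTANCE_SEED, ACCEPTANCE_B)


@pytest.fixture(scope="session")
def original_hpb(table1):
    """HPB distribution of the original cross-section table."""
    return _hpb(table1, ACCEPTANCE_SEED, ACCEPTANCE_B)


@pytest.fixture(scope="session")
def halflife3_hpb(halflife3):
    """Origin-tracked HPB distribution of the three recent half-life values."""
    return _hpb(halflife3, ACCEPTANCE_SEED, ACCEPTANCE_B, track=True)


# --- independent fixed-point oracle -----------------------------------------


def oracle_residual(x: np.ndarray, m: float, e2: float) -> tuple[float, float]:
    """The two MFV defining equations as residuals, written from scratch."""
    d2 = (x - m) ** 2
    w = 1.0 / (e2 + d2)
    r_loc = float((w * x).sum() / w.sum() - m)
    r_scale = float(3.0 * (d2 * w**2).sum() / (w**2).sum() - e2)
    return r_loc, r_scale


def oracle_fixed_points(x: np.ndarray, grid: int = 61) -> list[tuple[float, float]]:
    """All distinct fixed points found by dense grid search plus local root
    refinement over (location, dihesion^2)."""
    x = np.asarray(x, dtype=float)
    span = x.max() - x.min()
    assert span > 0, "oracle needs heterogeneous data"
    m_grid = np.linspace(x.min(), x.max(), grid)
    e_grid = np.linspace(span * 1e-3, span, grid)

    def system(p):
        return oracle_residual(x, p[0], p[1] ** 2)

    found: list[tuple[float, float]] = []
    # score the whole grid, then refine from the best-scoring cells
    scores = np.empty((grid, grid))
    for i, m0 in enumerate(m_grid):
        for j, e0 in enumerate(e_grid):
            r1, r2 = oracle_residual(x, m0, e0**2)
            scores[i, j] = abs(r1) / span + abs(r2) / span**2
    order = np.argsort(scores.ravel())
    for flat in order[: 5 * grid]:
        i, j = np.unravel_index(flat, scores.shape)
        sol = optimize.root(system, [m_grid[i], e_grid[j]], method="hybr")
        if not sol.success or sol.x[1] <= 0:
            continue
        m_star, eps_star = float(sol.x[0]), abs(float(sol.x[1]))
        r1, r2 = oracle_residual(x, m_star, eps_star**2)
        if abs(r1) > 1e-9 * max(1.0, span) or abs(r2) > 1e-9 * max(1.0, span**2):
            continue
        if not any(
            abs(m_star - m) <= 1e-7 * max(1.0, span) and abs(eps_star - e) <= 1e-7 * max(1.0, span)
            for m, e in found
        ):
            found.append((m_star, eps_star))
    return found
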