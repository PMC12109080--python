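"""Non-parametric and hybrid parametric bootstrap of the MFV.

The hybrid parametric bootstrap (HPB) quantifies the uncertainty of the MFV
for a table of measurements with stated 1-sigma uncertainties.  Each
replicate is built in two steps:

1. *Non-parametric*: draw n row indices uniformly with replacement from the
   table (capturing uncertainty about which measurements represent the
   population);
2. *Parametric*: replace each selected row by a draw from
   ``Normal(value, uncertainty)`` (capturing each measurement's own stated
   error).  Draws at or below ``lower_bound`` (default 0 — cross-sections
   and half-lives are strictly positive) are discarded and redrawn.

The MFV of the simulated sample is recorded; the empirical distribution of
the B replicate MFVs yields percentile confidence intervals.  The plain
non-parametric bootstrap (step 1 only) is provided for comparison.

Reproducibility contract: a single PCG64 stream (``numpy`` default) drives
a run.  It is consumed in a fixed, documented order — first the whole
B x n block of row indices, then (hybrid only) the B x n block of Gaussian
perturbations, then whole-array redraw sweeps over the out-of-bound cells.
Identical (table, settings, seed) therefore give bit-identical replicate
arrays, and a hybrid run whose uncertainties are all zero reproduces the
non-parametric run for the same seed exactly (the index block is drawn
first in both, and a Gaussian with scale 0 returns its mean).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .core import MFVEstimate, SolverSettings, mfv_solve, solve_batch
from .datasets import MeasurementTable

__all__ = [
    "BootstrapSettings",
    "BootstrapDistribution",
    "ConfidenceInterval",
    "TruncationError",
    "nonparametric_bootstrap_mfv",
    "hybrid_parametric_bootstrap_mfv",
    "draw_truncated_gaussian",
    "percentile_interval",
]

#: Replicate fraction above which a degenerate-replicate warning is attached.
DEGENERATE_WARN_FRACTION = 0.01


class TruncationError(RuntimeError):
    """Rejection sampling exhausted ``max_redraws`` for some measurement."""


@dataclass(frozen=True)
class BootstrapSettings:
    """Configuration of a bootstrap run.

    ``lower_bound`` is exclusive: a draw exactly at the bound is redrawn
    (zero is as unphysical as a negative cross-section).  Set it to
    ``None`` to disable truncation.  ``track_origins`` tags every simulated
    draw with its source-row index, enabling the per-origin validation
    diagnostics.
    """

    method: str = "hybrid"
    replicates: int = 100_000
    seed: int = 0
    lower_bound: float | None = 0.0
    max_redraws: int = 1000
    track_origins: bool = False
    solver: SolverSettings = field(default_factory=SolverSettings)

    def __post_init__(self) -> None:
        if self.method not in ("nonparametric", "hybrid"):
            raise ValueError("method must be 'nonparametric' or 'hybrid'")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.max_redraws < 1:
            raise ValueError("max_redraws must be >= 1")


@dataclass(frozen=True)
class BootstrapDistribution:
    """B replicate MFV values plus run metadata.

    ``origin_draws`` (when origins are tracked) maps each source-row index
    to the array of simulated values that were generated from it, across
    all replicates; the draw counts sum to ``B * n`` by construction.
    Replicates whose resample collapsed to a single distinct value (or
    whose solve did not converge) are counted in ``degenerate_count`` and
    contribute their last location estimate.
    """

    mfv_values: np.ndarray
    settings: BootstrapSettings
    point_estimate: MFVEstimate
    origin_draws: dict[int, np.ndarray] | None = None
    degenerate_count: int = 0
    warnings: tuple[str, ...] = ()

    def __len__(self) -> int:
        return len(self.mfv_values)


@dataclass(frozen=True)
class ConfidenceInterval:
    """Equal-tail percentile interval at a confidence level in (0, 1)."""

    level: float
    lower_prob: float
    upper_prob: float
    lower: float
    upper: float


def _check_table(table: MeasurementTable, need_uncertainties: bool) -> None:
    if need_uncertainties and not table.has_uncertainties:
        raise ValueError(
            "hybrid bootstrap requires an uncertainty for every row "
            f"(table {table.name!r} has rows without one)"
        )


def _solve_replicates(sim: np.ndarray, settings: BootstrapSettings):
    m, _, _, converged, degenerate = solve_batch(sim, settings.solver)
    bad = int((~converged & ~degenerate).sum() + degenerate.sum())
    warnings: tuple[str, ...] = ()
    if bad > DEGENERATE_WARN_FRACTION * len(sim):
        warnings = (
            f"{bad} of {len(sim)} replicates were degenerate or non-converged",
        )
    return m, bad, warnings


def nonparametric_bootstrap_mfv(
    table: MeasurementTable, settings: BootstrapSettings
) -> BootstrapDistribution:
    """Ordinary bootstrap: resample rows with replacement, MFV per replicate."""
    if settings.method != "nonparametric":
        raise ValueError("settings.method must be 'nonparametric'")
    values = table.values
    n = len(values)
    rng = np.random.default_rng(settings.seed)
    idx = rng.integers(0, n, size=(settings.replicates, n))
    sim = values[idx]
    m, bad, warnings = _solve_replicates(sim, settings)
    point = mfv_solve(values, settings.solver)
    return BootstrapDistribution(
        mfv_values=m,
        settings=settings,
        point_estimate=point,
        degenerate_count=bad,
        warnings=warnings,
    )


def hybrid_parametric_bootstrap_mfv(
    table: MeasurementTable, settings: BootstrapSettings
) -> BootstrapDistribution:
    """Hybrid parametric bootstrap: resample rows, then perturb each
    selected row by its own reported Gaussian uncertainty (with redraw of
    out-of-bound values), MFV per replicate."""
    if settings.method != "hybrid":
        raise ValueError("settings.method must be 'hybrid'")
    _check_table(table, need_uncertainties=True)
    values = table.values
    sds = table.uncertainties
    n = len(values)
    B = settings.replicates
    rng = np.random.default_rng(settings.seed)

    idx = rng.integers(0, n, size=(B, n))
    centers = values[idx]
    scales = sds[idx]
    draws = rng.normal(centers, scales)

    if settings.lower_bound is not None:
        bound = float(settings.lower_bound)
        for _ in range(settings.max_redraws):
            bad = draws <= bound
            if not bad.any():
                break
            draws[bad] = rng.normal(centers[bad], scales[bad])
        else:
            still_bad = draws <= bound
            if still_bad.any():
                offender = int(idx[still_bad][0])
                raise TruncationError(
                    f"row {offender} ({values[offender]} +/- {sds[offender]} "
                    f"{table.unit}) failed to produce a draw > {bound} in "
                    f"{settings.max_redraws} redraw sweeps"
                )

    m, bad_count, warnings = _solve_replicates(draws, settings)
    origin_draws = None
    if settings.track_origins:
        flat_idx = idx.ravel()
        flat_draws = draws.ravel()
        order = np.argsort(flat_idx, kind="stable")
        sorted_idx = flat_idx[order]
        sorted_draws = flat_draws[order]
        boundaries = np.searchsorted(sorted_idx, np.arange(n + 1))
        origin_draws = {
            i: sorted_draws[boundaries[i] : boundaries[i + 1]] for i in range(n)
        }

    point = mfv_solve(values, settings.solver)
    return BootstrapDistribution(
        mfv_values=m,
        settings=settings,
        point_estimate=point,
        origin_draws=origin_draws,
        degenerate_count=bad_count,
        warnings=warnings,
    )


def draw_truncated_gaussian(
    mean: float,
    sd: float,
    lower_bound: float | None,
    rng: np.random.Generator,
    size: int | None = None,
    max_redraws: int = 1000,
    return_rejections: bool = False,
):
    """Draw from ``Normal(mean, sd)`` restricted to ``(lower_bound, inf)``
    by rejection sampling (discard-and-redraw), the same rule the hybrid
    engine applies to simulated measurements.

    ``sd = 0`` returns ``mean`` (validated against the bound).  With
    ``size=None`` a scalar is returned; otherwise an array.  When
    ``return_rejections`` is true, also returns the number of rejected
    draws (for diagnostics on the truncation rate).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    scalar = size is None
    n = 1 if scalar else int(size)
    if sd == 0:
        if lower_bound is not None and mean <= lower_bound:
            raise TruncationError(
                f"degenerate draw: mean {mean} is not above bound {lower_bound}"
            )
        out = np.full(n, float(mean))
        rejections = 0
    else:
        out = rng.normal(mean, sd, size=n)
        rejections = 0
        if lower_bound is not None:
            bound = float(lower_bound)
            for _ in range(max_redraws):
                bad = out <= bound
                n_bad = int(bad.sum())
                if n_bad == 0:
                    break
                rejections += n_bad
                out[bad] = rng.normal(mean, sd, size=n_bad)
            else:
                if (out <= bound).any():
                    raise TruncationError(
                        f"no draw from Normal({mean}, {sd}) above {bound} "
                        f"after {max_redraws} redraw sweeps"
                    )
    result = float(out[0]) if scalar else out
    if return_rejections:
        return result, rejections
    return result


def percentile_interval(
    distribution: Sequence[float] | np.ndarray, level: float
) -> ConfidenceInterval:
    """Equal-tail percentile interval of a bootstrap distribution.

    The quantile probabilities are computed exactly from the level —
    ``(1 - level) / 2`` and ``1 - (1 - level) / 2`` (for the 68.27% level:
    0.15865 and 0.84135) — and evaluated with linear interpolation between
    order statistics (Hyndman-Fan type 7, numpy's default), fixed for
    bit-reproducibility.
    """
    if not 0.0 < level < 1.0:
        raise ValueError("level must be in (0, 1)")
    x = np.asarray(distribution, dtype=float)
    if x.size == 0:
        raise ValueError("percentile_interval requires a non-empty collection")
    lower_prob = (1.0 - level) / 2.0
    upper_prob = 1.0 - lower_prob
    lower, upper = np.quantile(x, [lower_prob, upper_prob], method="linear")
    return ConfidenceInterval(
        level=float(level),
        lower_prob=lower_prob,
        upper_prob=upper_prob,
        lower=float(lower),
        upper=float(upper),
    )
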