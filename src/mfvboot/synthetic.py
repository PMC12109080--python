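"""Seeded generators for synthetic measurement tables.

Three statistical structures exercise exactly the regimes the MFV/HPB
machinery targets:

* ``contaminated_gaussian`` — a Gaussian core with a fraction of points
  shifted by a fixed offset, the textbook outlier-contamination model under
  which the arithmetic mean breaks down but the MFV should not;
* ``cauchy`` — heavy tails with no finite mean, the substituting law
  itself, for consistency checks of the location estimate;
* ``heteroscedastic_table`` — per-row uncertainties drawn uniformly from a
  range, with each value drawn as ``Normal(location, u_i)``, mimicking a
  table of measurements of one quantity reported with varying precision.

Generators return :class:`~mfvboot.datasets.MeasurementTable` so synthetic
data flow through the same validation and bootstrap paths as real data.
They are statistical stand-ins only: no attempt is made to emulate
measurement systematics such as energy dependence or detector effects.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datasets import Measurement, MeasurementTable

__all__ = ["SyntheticSpec", "generate", "MODELS"]

MODELS = ("contaminated_gaussian", "cauchy", "heteroscedastic_table")


@dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for one synthetic table; deterministic given ``seed``."""

    model: str
    n: int
    location: float = 0.0
    scale: float = 1.0
    outlier_fraction: float = 0.0
    outlier_offset: float = 0.0
    uncertainty_range: tuple[float, float] = (0.5, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"model must be one of {MODELS}, got {self.model!r}")
        if self.n < 1:
            raise ValueError("n must be >= 1")
        if not self.scale > 0:
            raise ValueError("scale must be > 0")
        if not 0.0 <= self.outlier_fraction < 1.0:
            raise ValueError("outlier_fraction must be in [0, 1)")
        lo, hi = self.uncertainty_range
        if not (0 < lo <= hi):
            raise ValueError("uncertainty_range must be 0 < low <= high")


def generate(spec: SyntheticSpec) -> MeasurementTable:
    """Generate a measurement table according to ``spec``."""
    rng = np.random.default_rng(spec.seed)
    if spec.model == "contaminated_gaussian":
        is_outlier = rng.random(spec.n) < spec.outlier_fraction
        centers = np.where(is_outlier, spec.location + spec.outlier_offset, spec.location)
        values = rng.normal(centers, spec.scale)
        uncertainties = np.full(spec.n, spec.scale)
    elif spec.model == "cauchy":
        values = spec.location + spec.scale * rng.standard_cauchy(spec.n)
        uncertainties = np.ones(spec.n)  # placeholder: Cauchy has no 1-sigma
    else:  # heteroscedastic_table
        lo, hi = spec.uncertainty_range
        uncertainties = rng.uniform(lo, hi, size=spec.n)
        values = rng.normal(spec.location, uncertainties)
    rows = tuple(
        Measurement(value=float(v), uncertainty=float(u))
        for v, u in zip(values, uncertainties)
    )
    return MeasurementTable(name=f"synthetic_{spec.model}", unit="", rows=rows)
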