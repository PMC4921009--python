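"""Linear trends of haplotype statistics over generations.

Co-ancestry and proportion-segregating series are summarised by the slope
of a simple (ordinary least squares) linear regression of the statistic on
generation number, either over the full range or restricted to the first
few generations after the base (where the sharpest decay of segregating
ancestral haplotypes is expected).  Generation indices are taken as ordinal
offsets from the base generation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class TrendFit:
    """OLS fit of a per-generation statistic on generation number."""

    slope: float
    intercept: float
    r_squared: float
    n_points: int
    window: tuple[int, int]

    @property
    def slope_percent(self) -> float:
        """Slope expressed in percentage points per generation (x100)."""
        return 100.0 * self.slope


def fit_trend(
    series: pd.DataFrame | list[tuple[int, float]],
    window: tuple[int, int] | None = None,
    first_k: int | None = None,
) -> TrendFit:
    """Regress a (generation, value) series on generation number.

    ``series`` is a DataFrame whose first two columns are generation and
    value, or a list of pairs.  ``window=(lo, hi)`` keeps generations in
    the closed range; ``first_k=k`` keeps the base generation through
    base + k inclusive (so k = 3 regresses over 4 points when every
    generation is present).  ``window`` and ``first_k`` are exclusive.
    """
    if isinstance(series, pd.DataFrame):
        gens = series.iloc[:, 0].to_numpy(dtype=float)
        values = series.iloc[:, 1].to_numpy(dtype=float)
    else:
        arr = np.asarray(series, dtype=float)
        if arr.ndim != 2 or arr.shape[1] != 2:
            raise ValueError("series must be (generation, value) pairs")
        gens, values = arr[:, 0], arr[:, 1]
    if window is not None and first_k is not None:
        raise ValueError("give either window or first_k, not both")
    if first_k is not None:
        if first_k < 1:
            raise ValueError("first_k must be at least 1")
        base = gens.min()
        window = (int(base), int(base) + first_k)
    if window is not None:
        lo, hi = window
        mask = (gens >= lo) & (gens <= hi)
        gens, values = gens[mask], values[mask]
    if gens.size < 2:
        raise ValueError(f"need at least 2 points to fit a trend, got {gens.size}")
    if np.ptp(gens) == 0:
        raise ValueError("generation values are constant; slope undefined")
    fit = stats.linregress(gens, values)
    return TrendFit(
        slope=float(fit.slope),
        intercept=float(fit.intercept),
        r_squared=float(fit.rvalue) ** 2,
        n_points=int(gens.size),
        window=(int(gens.min()), int(gens.max())),
    )
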