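"""First-order decay fits to pulse-chase puncta time courses.

A pulse of labelled nascent protein is chased for several days; the mean
puncta count per cell at each chase day decays exponentially with the
protein's half-life. The natural log of the per-day mean count is fit by a
straight line *with* a free intercept (the initial puncta number is not
normalised to one, unlike the mass-spectrometric %old fractions), and the
half-life is ln(2)/k with k the negated slope. A nonlinear least-squares
variant fitting the exponential directly is available; the two differ only
slightly under noise.
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .types import PunctaFit

logger = logging.getLogger(__name__)

__all__ = ["fit_puncta_decay", "correlate_halflives"]


def fit_puncta_decay(table: pd.DataFrame, nonlinear: bool = False) -> PunctaFit:
    """Fit first-order decay to a per-cell puncta table.

    Computes the arithmetic mean puncta count per chase day over all cells
    (cells with zero puncta included — excluding them would bias the mean
    upward), drops days whose mean is not positive (warned), and requires
    at least three usable days. ``nonlinear=True`` fits
    ``n0 * exp(-k t)`` by least squares instead of the ln-linear form.
    """
    targets = table["target"].unique()
    if len(targets) != 1:
        raise ValueError(f"expected a single target, got {list(targets)}")
    per_day = table.groupby("chase_days")["puncta_count"].agg(["mean", "size"])
    usable = per_day["mean"] > 0
    if (~usable).any():
        logger.warning(
            "fit_puncta_decay(%s): dropping chase days with non-positive mean "
            "counts: %s", targets[0], list(per_day.index[~usable]),
        )
    per_day = per_day[usable]
    if len(per_day) < 3:
        raise ValueError(
            f"fit_puncta_decay({targets[0]}): need >=3 chase days with "
            f"positive mean counts, have {len(per_day)}"
        )
    days = per_day.index.to_numpy(dtype=float)
    means = per_day["mean"].to_numpy()

    if nonlinear:
        def model(t, n0, k):
            return n0 * np.exp(-k * t)

        (n0, k), _ = optimize.curve_fit(
            model, days, means, p0=(means[0], 0.5), maxfev=10000
        )
        predicted = model(days, n0, k)
        ss_res = float(np.sum((means - predicted) ** 2))
        ss_tot = float(np.sum((means - means.mean()) ** 2))
        r_squared = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        slope = -k
    else:
        fit = stats.linregress(days, np.log(means))
        slope = fit.slope
        r_squared = fit.rvalue**2
        k = -slope
    if k <= 0:
        raise ValueError(
            f"fit_puncta_decay({targets[0]}): non-positive rate constant "
            f"(slope {slope:.4g}); counts do not decay"
        )
    return PunctaFit(
        target=str(targets[0]),
        chase_days=tuple(days),
        mean_counts=tuple(float(m) for m in means),
        n_cells=tuple(int(n) for n in per_day["size"]),
        k_per_day=float(k),
        half_life_days=math.log(2.0) / float(k),
        r_squared=float(r_squared),
    )


def correlate_halflives(pairs) -> tuple[float, float]:
    """Pearson correlation between half-lives from two modalities.

    ``pairs`` is a sequence of (half-life by method A, half-life by method
    B); returns (r, two-sided p). Requires at least three pairs and
    non-degenerate variance in both coordinates.
    """
    arr = np.asarray(pairs, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2 or arr.shape[0] < 3:
        raise ValueError("need at least 3 (A, B) half-life pairs")
    if np.ptp(arr[:, 0]) == 0 or np.ptp(arr[:, 1]) == 0:
        raise ValueError("zero variance in one of the half-life vectors")
    result = stats.pearsonr(arr[:, 0], arr[:, 1])
    return float(result.statistic), float(result.pvalue)
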