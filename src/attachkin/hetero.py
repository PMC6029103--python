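"""Single-cell fluorescence heterogeneity statistics.

Works on background-subtracted per-cell intensities in arbitrary units
(a.u.).  The central heterogeneity measure is the coefficient of variation
(CV = sample SD / mean); threshold proportions, channel correlations,
Gaussian-kernel density summaries, CV-over-time trajectories and a thin
two-sample t-test wrapper round out the toolkit.
"""

from __future__ import annotations

from collections import namedtuple
from dataclasses import dataclass, field
from typing import Dict, Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError, StructuralError


@dataclass
class FluorTable:
    """Per-cell intensities by channel and population label.

    ``data`` holds one row per cell with at least ``cell_id``,
    ``population`` and one intensity column (``*_au``); an optional
    ``time_h`` column supports trajectories.  ``meta`` carries generator
    provenance (calibration flags etc.).
    """

    data: pd.DataFrame
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        if "population" not in self.data.columns:
            raise StructuralError("FluorTable requires a 'population' column")
        if self.data["population"].isna().any() or (self.data["population"] == "").any():
            raise StructuralError("population labels must be non-empty")
        if not self.channels:
            raise StructuralError("FluorTable requires at least one *_au channel")
        vals = self.data[self.channels].to_numpy(dtype=float)
        if not np.all(np.isfinite(vals)):
            raise StructuralError("intensities must be finite")

    @property
    def channels(self) -> list:
        return [c for c in self.data.columns if c.endswith("_au")]

    def intensities(self, channel: str, population: Optional[str] = None) -> np.ndarray:
        df = self.data
        if population is not None:
            df = df[df["population"] == population]
        if channel not in df.columns:
            raise StructuralError(f"no channel {channel!r}; have {self.channels}")
        return df[channel].to_numpy(dtype=float)

    def __len__(self) -> int:
        return len(self.data)


BackgroundResult = namedtuple("BackgroundResult", ["values", "n_clipped"])


def subtract_background(raw, background) -> BackgroundResult:
    """Subtract the mean background intensity, clipping at zero.

    Returns the corrected values and the number of cells clipped (a large
    clip count signals an implausible background estimate).
    """
    raw = np.asarray(raw, dtype=float)
    background = np.asarray(background, dtype=float)
    if np.any(background < 0):
        raise ParameterError("background must be nonnegative")
    diff = raw - background
    n_clipped = int(np.sum(diff < 0))
    return BackgroundResult(np.clip(diff, 0.0, None), n_clipped)


def cv(values) -> float:
    """Coefficient of variation: sample SD (n-1 denominator) over the mean."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ParameterError("cv requires at least 2 values")
    m = x.mean()
    if m <= 0:
        raise ParameterError(f"cv undefined for non-positive mean {m!r}")
    return float(x.std(ddof=1) / m)


FractionAbove = namedtuple("FractionAbove", ["proportion", "se", "n"])


def fraction_above(values, cutoff: float) -> FractionAbove:
    """Proportion of cells strictly above *cutoff*, with binomial SE."""
    x = np.asarray(values, dtype=float)
    if x.size < 1:
        raise ParameterError("fraction_above requires at least 1 value")
    p = float(np.mean(x > cutoff))
    se = float(np.sqrt(p * (1.0 - p) / x.size))
    return FractionAbove(p, se, int(x.size))


def channel_correlation(table: FluorTable, ch_a: str, ch_b: str,
                        population: Optional[str] = None):
    """Pearson correlation between two channels over paired cells.

    Returns ``(r, n)``.  Requires at least 3 paired cells and nonzero
    variance in both channels.
    """
    a = table.intensities(ch_a, population)
    b = table.intensities(ch_b, population)
    if len(a) < 3:
        raise ParameterError("channel correlation requires >= 3 paired cells")
    if np.std(a) == 0.0 or np.std(b) == 0.0:
        raise ParameterError("zero variance in a channel")
    r = stats.pearsonr(a, b).statistic
    return float(r), int(len(a))


def kde_100(values, n_points: int = 100):
    """Gaussian-kernel density estimate on an evenly spaced 100-point grid.

    Bandwidth follows Silverman's rule; the grid spans [min, max] of the
    sample.  Returns ``(grid, density)``.
    """
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise ParameterError("kde requires at least 2 values")
    kde = stats.gaussian_kde(x, bw_method="silverman")
    grid = np.linspace(x.min(), x.max(), n_points)
    return grid, kde(grid)


def cv_trajectory(table: FluorTable, channel: str,
                  population: Optional[str] = None) -> pd.DataFrame:
    """Per-timepoint CV of *channel*, sorted by ``time_h``.

    Each timepoint needs at least 2 cells.  Returns a DataFrame with
    columns ``time_h``, ``cv``, ``n``.
    """
    df = table.data
    if population is not None:
        df = df[df["population"] == population]
    if "time_h" not in df.columns:
        raise StructuralError("cv_trajectory requires a 'time_h' column")
    rows = []
    for t, grp in df.groupby("time_h"):
        rows.append({"time_h": float(t), "cv": cv(grp[channel]), "n": len(grp)})
    return pd.DataFrame(rows).sort_values("time_h").reset_index(drop=True)


def two_sample_test(a, b) -> dict:
    """Unpaired two-sided Student's t test (equal-variance), thin wrapper."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ParameterError("both samples need at least 2 values")
    res = stats.ttest_ind(a, b, equal_var=True)
    return {
        "t": float(res.statistic),
        "p": float(res.pvalue),
        "mean_a": float(a.mean()),
        "mean_b": float(b.mean()),
        "sd_a": float(a.std(ddof=1)),
        "sd_b": float(b.std(ddof=1)),
        "n_a": int(a.size),
        "n_b": int(b.size),
    }


@dataclass
class HeterogeneitySummary:
    """Moments, CV and threshold proportions of one population/channel."""

    n: int
    mean: float
    sd: float
    cv: float
    fractions_above: Dict[float, float]

    def __post_init__(self):
        if self.cv < 0:
            raise ParameterError("cv must be nonnegative")
        for p in self.fractions_above.values():
            if not 0.0 <= p <= 1.0:
                raise ParameterError("proportions must lie in [0, 1]")

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "mean_au": self.mean,
            "sd_au": self.sd,
            "cv": self.cv,
            "fractions_above": {str(int(c)): p for c, p in self.fractions_above.items()},
        }


def summarize(values, cutoffs: Sequence[float] = ()) -> HeterogeneitySummary:
    """One-stop heterogeneity summary of a single intensity sample."""
    x = np.asarray(values, dtype=float)
    return HeterogeneitySummary(
        n=int(x.size),
        mean=float(x.mean()),
        sd=float(x.std(ddof=1)) if x.size > 1 else 0.0,
        cv=cv(x),
        fractions_above={float(c): fraction_above(x, c).proportion for c in cutoffs},
    )
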