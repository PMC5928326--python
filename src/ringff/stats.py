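"""Validation statistics for simulated vs experimental liquid properties.

AVED (average deviation) is the mean of (simulated - experimental) over the
molecules of one property; the companion SD is the deviation scatter.  The
regression summary is an ordinary least squares of simulated on experimental
with a single outlier-exclusion pass: points whose residual from the
all-points fit exceeds 2 residual standard deviations are dropped, the line
is refit, and the Pearson R of the refit set is reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

__all__ = [
    "PROPERTY_NAMES", "BenchmarkEntry", "RegressionSummary",
    "aved", "regression_outlier_excluded",
]

PROPERTY_NAMES = frozenset(
    {"rho", "dHvap", "Cp_cla", "alpha_P", "kappa_T", "epsilon", "dG_hyd"}
)


@dataclass
class BenchmarkEntry:
    molecule: str
    property_name: str
    simulated: float
    experimental: float
    simulated_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.property_name not in PROPERTY_NAMES:
            raise ValueError(
                f"unknown property {self.property_name!r}; expected one of "
                f"{sorted(PROPERTY_NAMES)}"
            )


@dataclass
class RegressionSummary:
    slope: float
    intercept: float
    R: float
    n_used: int
    outlier_names: tuple[str, ...]


def _single_property(entries) -> list[BenchmarkEntry]:
    entries = list(entries)
    if not entries:
        raise ValueError("no entries")
    props = {e.property_name for e in entries}
    if len(props) > 1:
        raise ValueError(f"mixed properties in one statistic: {sorted(props)}")
    return entries


def aved(entries) -> tuple[float, float]:
    """Mean and SD of (simulated - experimental) for one property."""
    entries = _single_property(entries)
    dev = np.array([e.simulated - e.experimental for e in entries])
    sd = float(dev.std(ddof=1)) if dev.size > 1 else 0.0
    return float(dev.mean()), sd


def regression_outlier_excluded(entries) -> RegressionSummary:
    """OLS of simulated on experimental with one 2-SD residual exclusion pass.

    Outliers are points with |residual| > 2 * SD(residuals) of the initial
    all-points fit; the line and the Pearson R are recomputed on the kept set.
    """
    entries = _single_property(entries)
    if len(entries) < 3:
        raise ValueError("regression needs at least 3 entries")
    x = np.array([e.experimental for e in entries])
    y = np.array([e.simulated for e in entries])
    fit0 = sps.linregress(x, y)
    resid = y - (fit0.slope * x + fit0.intercept)
    sd = resid.std(ddof=1)
    keep = np.abs(resid) <= 2.0 * sd if sd > 0 else np.ones_like(resid, dtype=bool)
    if not keep.any():
        raise ValueError("all points excluded as outliers")
    outliers = tuple(e.molecule for e, k in zip(entries, keep) if not k)
    fit = sps.linregress(x[keep], y[keep])
    r = float(sps.pearsonr(x[keep], y[keep]).statistic) if keep.sum() > 2 else float(fit.rvalue)
    return RegressionSummary(
        slope=float(fit.slope), intercept=float(fit.intercept), R=r,
        n_used=int(keep.sum()), outlier_names=outliers,
    )
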