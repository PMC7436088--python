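"""Comparison of per-frame probe-membrane binding-energy series.

The probe's binding energy to each membrane/water system is an input (an
MD-engine product, read from CSV); this module only tests whether two
systems differ.  The test is Welch's unequal-variance t with
Welch-Satterthwaite degrees of freedom, two-sided, and the significance
rule is the ">98% probability" convention: significant iff 1 - p exceeds
the confidence threshold (strict inequality).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ConfigurationError, DegenerateDataError
from .topology import SystemLabel

DEFAULT_CONFIDENCE = 0.98


@dataclass
class EnergySeries:
    """Per-frame binding energies (kcal/mol) for one system."""

    values: np.ndarray
    times: np.ndarray  # ns
    label: SystemLabel | str | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        if self.values.shape != self.times.shape:
            raise ConfigurationError("values and times must align")
        if not np.all(np.isfinite(self.values)):
            raise ConfigurationError("energies must be finite")
        if len(self.times) > 1 and np.any(np.diff(self.times) <= 0):
            raise ConfigurationError("times must be strictly increasing")

    @classmethod
    def from_csv(cls, path: str | Path, label=None) -> "EnergySeries":
        df = pd.read_csv(path)
        return cls(df["energy_kcal_mol"].to_numpy(), df["time_ns"].to_numpy(),
                   label=label if label is not None else df.get("system", pd.Series([None])).iloc[0])

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({
            "system": [str(self.label)] * len(self.values),
            "time_ns": self.times,
            "energy_kcal_mol": self.values,
        }).to_csv(path, index=False)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float


def welch_t_test(a: EnergySeries | np.ndarray, b: EnergySeries | np.ndarray) -> TTestResult:
    """Welch's two-sided t-test on two energy series."""
    x = a.values if isinstance(a, EnergySeries) else np.asarray(a, dtype=float)
    y = b.values if isinstance(b, EnergySeries) else np.asarray(b, dtype=float)
    if len(x) < 2 or len(y) < 2:
        raise DegenerateDataError("each series needs at least 2 observations")
    if x.var(ddof=1) == 0.0 and y.var(ddof=1) == 0.0 and x.mean() == y.mean():
        raise DegenerateDataError("both series constant and equal: test undefined")
    res = sps.ttest_ind(x, y, equal_var=False)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


@dataclass
class SignificanceReport:
    t: float
    df: float
    p: float
    one_minus_p: float
    threshold: float
    significant: bool

    def to_dict(self) -> dict:
        return {
            "t": self.t, "df": self.df, "p": self.p,
            "one_minus_p": self.one_minus_p,
            "threshold": self.threshold, "significant": self.significant,
        }


def significance_report(
    p: float, confidence_threshold: float = DEFAULT_CONFIDENCE,
    *, t: float = np.nan, df: float = np.nan,
) -> SignificanceReport:
    """Apply the confidence rule: significant iff (1 - p) > threshold."""
    if not 0.0 < p <= 1.0:
        raise ConfigurationError(f"p must lie in (0, 1], got {p}")
    if not 0.0 < confidence_threshold < 1.0:
        raise ConfigurationError("confidence threshold must lie in (0, 1)")
    return SignificanceReport(
        t=t, df=df, p=p, one_minus_p=1.0 - p,
        threshold=confidence_threshold,
        significant=(1.0 - p) > confidence_threshold,
    )


def compare_energies(
    a: EnergySeries, b: EnergySeries, confidence_threshold: float = DEFAULT_CONFIDENCE
) -> SignificanceReport:
    """Welch test + significance verdict in one call."""
    res = welch_t_test(a, b)
    return significance_report(res.p, confidence_threshold, t=res.t, df=res.df)
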