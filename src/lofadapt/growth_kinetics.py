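"""Doubling-time estimation from growth curves and strain comparison.

A growth curve is a series of absorbance readings (OD600) with a blank
background and, for cultures kept in exponential phase by serial
dilution, the cumulative dilution factor applied before each reading.
Exponential-phase doubling time is the inverse slope of a least-squares
line on log2(background-corrected absorbance x cumulative dilution)
versus time; fits are accepted only above a configurable r^2 (0.99 for
plate-window fits, 0.95 for serial-dilution fits by default).

Strains are compared to the parent with one- or two-sided Mann-Whitney
rank-sum tests (exact for small groups, normal approximation otherwise)
and a Benjamini-Hochberg correction across all strain/media tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "GrowthCurve",
    "DoublingTimeFit",
    "fit_doubling_time",
    "compare_strains",
    "read_growth_csv",
    "write_growth_csv",
    "R2_MIN_PLATE",
    "R2_MIN_DILUTION",
]

R2_MIN_PLATE = 0.99
R2_MIN_DILUTION = 0.95
EXACT_MW_MAX = 10  # per-group size up to which the exact test is used


@dataclass
class GrowthCurve:
    """Timestamped absorbance readings with blank and dilution bookkeeping."""

    times: np.ndarray  # minutes
    absorbance: np.ndarray
    blank: float = 0.0
    cumulative_dilution: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.absorbance = np.asarray(self.absorbance, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.absorbance.shape:
            raise ValueError("times and absorbance must be equal-length vectors")
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("sample times must be strictly increasing")
        if self.cumulative_dilution is None:
            self.cumulative_dilution = np.ones_like(self.times)
        else:
            self.cumulative_dilution = np.asarray(self.cumulative_dilution, dtype=float)
            if self.cumulative_dilution.shape != self.times.shape:
                raise ValueError("cumulative_dilution must match sample times")
            if np.any(self.cumulative_dilution < 1):
                raise ValueError("cumulative dilution factors must be >= 1")
            if np.any(np.diff(self.cumulative_dilution) < 0):
                raise ValueError("cumulative dilution must be non-decreasing")

    @property
    def corrected(self) -> np.ndarray:
        """Background-corrected absorbance (before dilution correction)."""
        return self.absorbance - self.blank

    @property
    def effective(self) -> np.ndarray:
        """Dilution-corrected population signal: (A - blank) x cumulative dilution."""
        return self.corrected * self.cumulative_dilution


@dataclass
class DoublingTimeFit:
    doubling_time: float  # minutes
    r_squared: float
    window: tuple[int, int]  # [start, stop) sample indices used
    accepted: bool
    n_points: int


def _select_window(curve: GrowthCurve, window_rule) -> np.ndarray:
    """Resolve a window rule to sample indices.

    Rules: ("absorbance_range", lo, hi) on the background-corrected (pre-
    dilution) absorbance, or ("manual", indices).
    """
    kind = window_rule[0]
    if kind == "absorbance_range":
        _, lo, hi = window_rule
        mask = (curve.corrected >= lo) & (curve.corrected <= hi)
        return np.nonzero(mask)[0]
    if kind == "manual":
        return np.asarray(window_rule[1], dtype=int)
    raise ValueError(f"unknown window rule {kind!r}")


def fit_doubling_time(
    curve: GrowthCurve,
    window_rule=("absorbance_range", 0.015625, 0.0625),
    r2_min: float = R2_MIN_PLATE,
) -> DoublingTimeFit:
    """Least-squares doubling time over the selected window.

    Fits log2((A - blank) x cumulative dilution) against time; the slope
    is doublings per minute, so its inverse is the doubling time.  The fit
    is accepted only when r^2 >= r2_min.
    """
    idx = _select_window(curve, window_rule)
    if idx.size < 3:
        raise ValueError(f"window contains {idx.size} points; >=3 required")
    y = curve.effective[idx]
    bad = int(np.sum(y <= 0))
    if bad:
        raise ValueError(f"{bad} non-positive corrected values in window")
    t = curve.times[idx]
    slope, intercept = np.polyfit(t, np.log2(y), 1)
    pred = slope * t + intercept
    resid = np.log2(y) - pred
    ss_tot = float(np.sum((np.log2(y) - np.log2(y).mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    if slope <= 0:
        raise ValueError("no growth in window (non-positive slope)")
    return DoublingTimeFit(
        doubling_time=1.0 / slope,
        r_squared=r2,
        window=(int(idx.min()), int(idx.max()) + 1),
        accepted=r2 >= r2_min,
        n_points=int(idx.size),
    )


def read_growth_csv(path) -> dict[tuple[str, str, str], GrowthCurve]:
    """Read curves keyed by (strain, media, replicate) from a CSV with
    columns time, absorbance, blank, cumulative_dilution, strain, media,
    replicate."""
    df = pd.read_csv(path)
    out: dict[tuple[str, str, str], GrowthCurve] = {}
    for key, grp in df.groupby(["strain", "media", "replicate"], sort=False):
        grp = grp.sort_values("time")
        out[tuple(str(k) for k in key)] = GrowthCurve(
            times=grp["time"].to_numpy(),
            absorbance=grp["absorbance"].to_numpy(),
            blank=float(grp["blank"].iloc[0]),
            cumulative_dilution=grp["cumulative_dilution"].to_numpy(),
        )
    return out


def write_growth_csv(
    curves: Mapping[tuple[str, str, str], GrowthCurve], path
) -> None:
    rows = []
    for (strain, media, rep), c in curves.items():
        for t, a, d in zip(c.times, c.absorbance, c.cumulative_dilution):
            rows.append((t, a, c.blank, d, strain, media, rep))
    pd.DataFrame(
        rows,
        columns=[
            "time",
            "absorbance",
            "blank",
            "cumulative_dilution",
            "strain",
            "media",
            "replicate",
        ],
    ).to_csv(path, index=False)


def _mannwhitney(
    mutant: np.ndarray, parent: np.ndarray, sided: str
) -> tuple[float, float]:
    """U statistic and p-value; one-sided tests the mutant being faster
    (smaller doubling times)."""
    alternative = "less" if sided == "one" else "two-sided"
    if len(np.unique(np.concatenate([mutant, parent]))) == 1:
        import warnings

        warnings.warn("all observations tied; p set to 1", stacklevel=2)
        u = len(mutant) * len(parent) / 2.0
        return u, 1.0
    exact = (
        len(mutant) <= EXACT_MW_MAX
        and len(parent) <= EXACT_MW_MAX
        and len(np.unique(np.concatenate([mutant, parent])))
        == len(mutant) + len(parent)
    )
    res = stats.mannwhitneyu(
        mutant, parent, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def compare_strains(
    mutant_fits: Mapping[str, Sequence[float]],
    parent_fits: Sequence[float],
    sided: str = "one",
    target_fdr: float = 0.05,
) -> pd.DataFrame:
    """Rank-sum comparison of each mutant's doubling times to the parent's.

    Returns a strain-indexed DataFrame with columns ``U, p, q,
    significant`` (BH across all strains at ``target_fdr``); one-sided
    tests for faster growth (shorter doubling time).
    """
    if sided not in {"one", "two"}:
        raise ValueError("sided must be 'one' or 'two'")
    parent = np.asarray(parent_fits, dtype=float)
    if parent.size < 2:
        raise ValueError("need >=2 parent measurements")
    rows = []
    for strain, fits in mutant_fits.items():
        m = np.asarray(fits, dtype=float)
        if m.size < 2:
            raise ValueError(f"strain {strain!r}: need >=2 measurements")
        u, p = _mannwhitney(m, parent, sided)
        rows.append((strain, u, p))
    table = pd.DataFrame(rows, columns=["strain", "U", "p"]).set_index("strain")
    reject, q, _, _ = multipletests(table["p"], alpha=target_fdr, method="fdr_bh")
    table["q"] = q
    table["significant"] = reject
    return table
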