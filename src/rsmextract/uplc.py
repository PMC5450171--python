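"""Chromatographic calibration, quantification and system suitability.

Covers the UPLC workflow of the extraction study: external-standard
linear calibration per analyte (for linearity and range validation),
one-point external-standard content computation, and system-suitability
precision metrics -- relative standard deviations (RSD) of relative
retention time (RRT) and relative peak area (RPA) across replicate
injections, referenced to a designated peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CalibrationCurve",
    "PeakTable",
    "SuitabilityReport",
    "fit_calibration",
    "quantify_one_point",
    "suitability",
    "suitability_report",
    "total_content",
    "read_peak_tables",
]


@dataclass(frozen=True)
class CalibrationCurve:
    """Linear standard curve ``area = slope * conc + intercept`` with its
    valid concentration range (ug/mL)."""

    analyte: str
    slope: float
    intercept: float
    r_squared: float
    range_low: float
    range_high: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0:
            raise ValueError("R^2 must lie in [0, 1]")
        if not self.range_low < self.range_high:
            raise ValueError("linear range must satisfy low < high")

    def area(self, conc: float) -> float:
        return self.slope * conc + self.intercept

    def conc(self, area: float) -> float:
        if self.slope == 0:
            raise ValueError("zero slope: concentration is not identifiable")
        return (area - self.intercept) / self.slope

    def in_range(self, conc: float) -> bool:
        return self.range_low <= conc <= self.range_high


def fit_calibration(points, analyte: str = "", rng: tuple[float, float] | None = None) -> CalibrationCurve:
    """Least-squares calibration line from (concentration, area) pairs.

    Needs at least 3 points with at least 2 distinct concentrations; the
    valid range defaults to the span of the standards.  R^2 is defined as
    0 for constant areas.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (concentration, area) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("all concentrations identical; calibration undefined")
    sxx = np.sum((x - x.mean()) ** 2)
    slope = float(np.sum((x - x.mean()) * (y - y.mean())) / sxx)
    intercept = float(y.mean() - slope * x.mean())
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0:
        r2 = 0.0
    else:
        r2 = float(1.0 - np.sum((y - (slope * x + intercept)) ** 2) / ss_tot)
        r2 = min(max(r2, 0.0), 1.0)
    lo, hi = (float(x.min()), float(x.max())) if rng is None else map(float, rng)
    return CalibrationCurve(analyte, slope, intercept, r2, lo, hi)


@dataclass
class PeakTable:
    """Peak areas and retention times for one injection.

    ``peaks`` has columns ``peak`` (unique integer label), ``t_r``
    (retention time, min, strictly positive and increasing with peak
    number) and ``area``.
    """

    injection_id: str
    peaks: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"peak", "t_r", "area"}
        if not required.issubset(self.peaks.columns):
            raise ValueError(f"peak table needs columns {sorted(required)}")
        self.peaks = self.peaks.sort_values("peak").reset_index(drop=True)
        if self.peaks["peak"].duplicated().any():
            raise ValueError(f"injection {self.injection_id}: duplicate peak numbers")
        t = self.peaks["t_r"].to_numpy(dtype=float)
        if np.any(t <= 0) or np.any(np.diff(t) <= 0):
            raise ValueError(
                f"injection {self.injection_id}: retention times must be positive "
                "and increasing with peak number"
            )

    def relative_to(self, reference_peak: int) -> pd.DataFrame:
        """RRT and RPA of every peak against the reference peak."""
        ref = self.peaks[self.peaks["peak"] == reference_peak]
        if ref.empty:
            raise ValueError(
                f"injection {self.injection_id}: reference peak {reference_peak} missing"
            )
        t_ref = float(ref["t_r"].iloc[0])
        a_ref = float(ref["area"].iloc[0])
        out = self.peaks[["peak"]].copy()
        out["rrt"] = self.peaks["t_r"] / t_ref
        out["rpa"] = self.peaks["area"] / a_ref
        return out


def _rsd(x: np.ndarray) -> float:
    """Percent relative standard deviation with the sample (n-1) sd."""
    m = x.mean()
    if m == 0:
        raise ValueError("mean is zero; RSD undefined")
    return float(100.0 * x.std(ddof=1) / m)


def suitability(tables: list[PeakTable], reference_peak: int) -> pd.DataFrame:
    """Per-peak RSDs of RRT and RPA across replicate injections.

    Returns a frame indexed by peak number with columns ``rsd_rrt`` and
    ``rsd_rpa``; the reference peak's rows are exactly 0 by construction.
    """
    if len(tables) < 2:
        raise ValueError("need at least 2 injections to compute RSDs")
    rel = []
    for t in tables:
        r = t.relative_to(reference_peak)
        r["injection"] = t.injection_id
        rel.append(r)
    combined = pd.concat(rel)
    counts = combined.groupby("peak").size()
    if counts.nunique() > 1:
        raise ValueError("peak sets differ across injections")
    out = combined.groupby("peak").agg(
        rsd_rrt=("rrt", lambda v: _rsd(v.to_numpy())),
        rsd_rpa=("rpa", lambda v: _rsd(v.to_numpy())),
    )
    # the reference peak's ratios are identically 1; force exact zeros
    out.loc[reference_peak] = [0.0, 0.0]
    return out


@dataclass
class SuitabilityReport:
    """RSD summaries for named injection sets (precision/stability/...).

    ``sets`` maps a set label to the per-peak frame from
    :func:`suitability`.
    """

    reference_peak: int
    sets: dict[str, pd.DataFrame]

    def to_frame(self) -> pd.DataFrame:
        parts = []
        for label, df in self.sets.items():
            parts.append(df.rename(columns={c: f"{c.replace('rsd_', '')}_{label}" for c in df.columns}))
        return pd.concat(parts, axis=1)


def suitability_report(
    injection_sets: dict[str, list[PeakTable]], reference_peak: int
) -> SuitabilityReport:
    """Run :func:`suitability` on each named set of injections."""
    return SuitabilityReport(
        reference_peak=reference_peak,
        sets={label: suitability(tabs, reference_peak) for label, tabs in injection_sets.items()},
    )


def quantify_one_point(
    sample_area: float,
    standard_area: float,
    standard_conc: float,
    volume_ml: float,
    mass_mg: float,
    dilution: float = 1.0,
    curve: CalibrationCurve | None = None,
) -> float:
    """One-point external-standard content in percent w/w.

    The sample concentration is ``sample_area / standard_area *
    standard_conc`` (ug/mL); the content converts it through the sample
    solution volume (mL), dilution factor and weighed extract mass (mg).
    When a :class:`CalibrationCurve` is supplied, a concentration outside
    its linear range triggers a warning.
    """
    if standard_area <= 0:
        raise ValueError("standard area must be positive")
    if mass_mg <= 0:
        raise ValueError("extract mass must be positive")
    if sample_area < 0 or standard_conc <= 0 or volume_ml <= 0 or dilution <= 0:
        raise ValueError("areas must be non-negative; conc/volume/dilution positive")
    conc = sample_area / standard_area * standard_conc
    if curve is not None and not curve.in_range(conc):
        warnings.warn(
            f"implied concentration {conc:.2f} ug/mL outside the linear range "
            f"[{curve.range_low}, {curve.range_high}] of {curve.analyte or 'analyte'}",
            stacklevel=2,
        )
    # ug analyte = conc * volume * dilution; mass in ug = mass_mg * 1000
    return conc * volume_ml * dilution / (mass_mg * 1000.0) * 100.0


def total_content(contents) -> float:
    """Sum of per-component percent contents."""
    arr = np.asarray(list(contents), dtype=float)
    if arr.size and np.any(arr < 0):
        raise ValueError("contents must be non-negative")
    return float(arr.sum())


def read_peak_tables(path_or_df) -> list[PeakTable]:
    """Load peak tables from CSV with columns
    ``injection_id, peak, t_r_min, area`` (one row per peak)."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    df = df.rename(columns={"t_r_min": "t_r"})
    required = {"injection_id", "peak", "t_r", "area"}
    if not required.issubset(df.columns):
        raise ValueError(f"peak CSV needs columns {sorted(required)}")
    return [
        PeakTable(injection_id=str(inj), peaks=g[["peak", "t_r", "area"]].copy())
        for inj, g in df.groupby("injection_id", sort=False)
    ]
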