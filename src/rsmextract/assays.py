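"""Assay response computations.

The five responses of the extraction study are all simple ratios of raw
measurements: extraction yield (mass ratio), total polyphenol content
(gallic-acid-equivalent concentration ratio), enzyme inhibition rate
(PTP-1B with pNPP, alpha-glucosidase with pNPG) and radical-scavenging
inhibition rate (ABTS, DPPH), the last two computed from blank-corrected
absorbances.  Blank correction is the caller's responsibility.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssayMeasurement",
    "extraction_yield",
    "tpc_percent",
    "inhibition_rate_enzyme",
    "inhibition_rate_radical",
    "linear_gae_calibration",
    "LineFit",
]

_KINDS = ("extraction_weights", "tpc_pair", "enzyme_pair", "radical_pair")


@dataclass
class AssayMeasurement:
    """One raw measurement: a named pair of weights, concentrations or
    blank-corrected absorbances, tagged with the assay it came from."""

    kind: str
    values: dict[str, float]
    sample_conc: float | None = None  # ug/mL, metadata only

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown assay kind {self.kind!r}; expected one of {_KINDS}")
        if self.kind in ("extraction_weights", "tpc_pair"):
            if any(v <= 0 for k, v in self.values.items() if k in ("W2", "C2")):
                raise ValueError("denominator weight/concentration must be positive")
        if any(v < 0 for v in self.values.values()):
            raise ValueError("raw measurements must be non-negative")

    def response(self) -> float:
        """Dispatch to the response formula for this measurement's kind."""
        v = self.values
        if self.kind == "extraction_weights":
            return extraction_yield(v["W1"], v["W2"])
        if self.kind == "tpc_pair":
            return tpc_percent(v["C1"], v["C2"])
        if self.kind == "enzyme_pair":
            return inhibition_rate_enzyme(v["control"], v["sample"])
        return inhibition_rate_radical(v["blank"], v["sample"])


def extraction_yield(w1: float, w2: float) -> float:
    """Extraction yield in percent: dried-extract mass over raw-material mass.

    Parameters are in grams; ``w2`` (mass before extraction) must be
    positive.  Yields above 100% are physically suspect and trigger a
    warning but are returned as computed.
    """
    if w2 <= 0:
        raise ValueError("mass before extraction (w2) must be positive")
    if w1 < 0:
        raise ValueError("mass after extraction (w1) must be non-negative")
    ey = w1 / w2 * 100.0
    if ey > 100.0:
        warnings.warn(f"extraction yield {ey:.2f}% exceeds 100%", stacklevel=2)
    return ey


def tpc_percent(c1: float, c2: float) -> float:
    """Total polyphenol content in percent: gallic-acid equivalents (ug/mL)
    over total sample concentration (ug/mL)."""
    if c2 <= 0:
        raise ValueError("total sample concentration (c2) must be positive")
    return c1 / c2 * 100.0


def inhibition_rate_enzyme(control_abs: float, sample_abs: float) -> float:
    """Enzyme inhibition rate in percent: ``(control - sample)/control * 100``.

    Used for both the PTP-1B (pNPP substrate) and alpha-glucosidase (pNPG
    substrate) endpoint assays.  Negative values mean apparent activation
    and are returned as-is with a warning.
    """
    if control_abs <= 0:
        raise ValueError("control absorbance must be positive")
    ir = (control_abs - sample_abs) / control_abs * 100.0
    if ir < 0:
        warnings.warn(f"negative inhibition rate {ir:.2f}% (activation?)", stacklevel=2)
    return ir


def inhibition_rate_radical(blank_abs: float, sample_abs: float) -> float:
    """Radical-scavenging inhibition rate in percent (ABTS/DPPH convention).

    ``(A_blank - A_sample)/A_blank * 100``: the fractional loss of radical
    absorbance caused by the sample.
    """
    if blank_abs <= 0:
        raise ValueError("blank absorbance must be positive")
    ir = (blank_abs - sample_abs) / blank_abs * 100.0
    if ir < 0:
        warnings.warn(f"negative scavenging rate {ir:.2f}%", stacklevel=2)
    return ir


@dataclass(frozen=True)
class LineFit:
    slope: float
    intercept: float
    r_squared: float


def linear_gae_calibration(points) -> LineFit:
    """Least-squares standard line for the gallic-acid calibration.

    ``points`` is an iterable of (concentration ug/mL, absorbance) pairs;
    at least 3 distinct concentrations are required.  R^2 is
    ``1 - SS_res/SS_tot`` and defined as 0 when the absorbances are
    constant.
    """
    pts = np.asarray(list(points), dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (concentration, absorbance) pairs")
    x, y = pts[:, 0], pts[:, 1]
    if np.unique(x).size < 2:
        raise ValueError("all concentrations identical; line undefined")
    sxx = np.sum((x - x.mean()) ** 2)
    slope = np.sum((x - x.mean()) * (y - y.mean())) / sxx
    intercept = y.mean() - slope * x.mean()
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        return LineFit(float(slope), float(intercept), 0.0)
    ss_res = np.sum((y - (slope * x + intercept)) ** 2)
    return LineFit(float(slope), float(intercept), float(1.0 - ss_res / ss_tot))
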