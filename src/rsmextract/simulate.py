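"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the data-generating structure assumed by the
analysis: responses are a known quadratic surface plus iid Gaussian
noise (so replicated center runs share one mean and their scatter is the
pure error); assay plates add Gaussian absorbance noise around a known
true inhibition; chromatographic injections perturb a template's peak
areas by iid lognormal factors of specified CV (areas stay positive) and
jitter retention times with a Gaussian sd; calibration series are a
known line plus Gaussian area noise.  Seeds are mandatory: no hidden
global random state.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .assays import AssayMeasurement
from .factors import DesignTable, FactorSpec, make_bbd
from .model import QuadraticModel
from .uplc import PeakTable

__all__ = [
    "SimulationScenario",
    "ChromatogramTemplate",
    "CalibrationTruth",
    "gen_bbd_experiment",
    "gen_assay_plate",
    "gen_injections",
    "gen_calibration",
]


@dataclass
class ChromatogramTemplate:
    """True peak layout for replicate-injection simulation.

    ``area_cv`` is the percent coefficient of variation of the lognormal
    multiplicative area noise; ``rt_sd_min`` the Gaussian retention-time
    jitter in minutes.
    """

    retention_times: np.ndarray  # min, strictly increasing
    areas: np.ndarray
    reference_peak: int = 1
    area_cv: float = 1.0  # percent
    rt_sd_min: float = 0.0

    def __post_init__(self) -> None:
        self.retention_times = np.asarray(self.retention_times, dtype=float)
        self.areas = np.asarray(self.areas, dtype=float)
        if self.retention_times.size < 2:
            raise ValueError("template needs at least 2 peaks")
        if self.retention_times.size != self.areas.size:
            raise ValueError("retention times and areas must align")
        if not 1 <= self.reference_peak <= self.retention_times.size:
            raise ValueError("reference peak outside the template")
        if self.area_cv < 0 or self.rt_sd_min < 0:
            raise ValueError("noise parameters must be >= 0")


@dataclass
class CalibrationTruth:
    """True line area = slope * conc + intercept over [range_low, range_high]."""

    slope: float
    intercept: float
    range_low: float
    range_high: float
    noise_sd: float = 0.0  # area units

    def __post_init__(self) -> None:
        if not self.range_low < self.range_high:
            raise ValueError("range must satisfy low < high")
        if self.noise_sd < 0:
            raise ValueError("noise sd must be >= 0")


@dataclass
class SimulationScenario:
    """Everything needed to simulate one BBD experiment with known truth.

    ``true_models`` maps response names to the surfaces that generate
    them; ``noise_sd`` gives each response's iid error sd (responses not
    listed default to 0).
    """

    factors: list[FactorSpec]
    true_models: dict[str, QuadraticModel]
    noise_sd: dict[str, float] = field(default_factory=dict)
    n_center: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise sds must be >= 0")
        names = [f.name for f in self.factors]
        for rname, m in self.true_models.items():
            if [f.name for f in m.factors] != names:
                raise ValueError(f"model {rname!r} does not match the scenario factors")


def gen_bbd_experiment(scenario: SimulationScenario):
    """Simulate a Box-Behnken experiment from known surfaces.

    Returns ``(DesignTable, DataFrame)`` with one response column per
    true model; responses are surface value plus iid N(0, sd^2) noise, so
    all center replicates share the same mean.  Fully determined by
    ``scenario.seed``.
    """
    design = make_bbd(scenario.factors, n_center=scenario.n_center)
    rng = np.random.default_rng(scenario.seed)
    cols = {}
    for rname, model in scenario.true_models.items():
        mean = model.predict(design.coded)
        sd = scenario.noise_sd.get(rname, 0.0)
        cols[rname] = mean + (rng.normal(0.0, sd, size=design.n_runs) if sd > 0 else 0.0)
    responses = pd.DataFrame(cols)
    responses.insert(0, "run_id", design.run_ids)
    return design, responses


def gen_assay_plate(
    true_inhibition: float, control_abs: float, sd: float, n: int, seed: int
) -> list[AssayMeasurement]:
    """Simulate ``n`` enzyme-assay wells at a known true inhibition rate.

    Sample absorbances are ``control * (1 - IR/100)`` plus N(0, sd^2)
    noise, clipped at 0 (absorbances cannot be negative).
    """
    if not 0.0 <= true_inhibition <= 100.0:
        raise ValueError("true inhibition must be in [0, 100] percent")
    if control_abs <= 0 or sd < 0 or n < 1:
        raise ValueError("need control_abs > 0, sd >= 0, n >= 1")
    rng = np.random.default_rng(seed)
    base = control_abs * (1.0 - true_inhibition / 100.0)
    samples = np.clip(base + rng.normal(0.0, sd, size=n), 0.0, None)
    return [
        AssayMeasurement(kind="enzyme_pair", values={"control": control_abs, "sample": float(s)})
        for s in samples
    ]


def gen_injections(template: ChromatogramTemplate, n: int, seed: int) -> list[PeakTable]:
    """Simulate ``n`` replicate injections of a chromatogram template.

    Areas are multiplied by iid lognormal factors with unit mean and the
    template's CV; retention times get iid Gaussian jitter (the whole
    profile stays ordered for small jitter -- a violation raises from
    :class:`PeakTable` validation).
    """
    if n < 1:
        raise ValueError("need n >= 1 injections")
    rng = np.random.default_rng(seed)
    n_peaks = template.areas.size
    cv = template.area_cv / 100.0
    sigma2 = np.log1p(cv**2)
    tables = []
    for i in range(n):
        if cv > 0:
            factors = rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=n_peaks)
        else:
            factors = np.ones(n_peaks)
        t_r = template.retention_times + (
            rng.normal(0.0, template.rt_sd_min, size=n_peaks) if template.rt_sd_min > 0 else 0.0
        )
        tables.append(
            PeakTable(
                injection_id=f"inj{i + 1}",
                peaks=pd.DataFrame(
                    {
                        "peak": np.arange(1, n_peaks + 1),
                        "t_r": t_r,
                        "area": template.areas * factors,
                    }
                ),
            )
        )
    return tables


def gen_calibration(truth: CalibrationTruth, n_points: int, seed: int) -> pd.DataFrame:
    """Simulate a calibration series on an evenly spaced concentration grid.

    Returns a frame with ``conc`` (ug/mL) and ``area`` columns; areas are
    the true line plus N(0, noise_sd^2).
    """
    if n_points < 3:
        raise ValueError("need at least 3 calibration points")
    rng = np.random.default_rng(seed)
    conc = np.linspace(truth.range_low, truth.range_high, n_points)
    area = truth.slope * conc + truth.intercept
    if truth.noise_sd > 0:
        area = area + rng.normal(0.0, truth.noise_sd, size=n_points)
    return pd.DataFrame({"conc": conc, "area": area})
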