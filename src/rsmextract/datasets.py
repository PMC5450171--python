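"""Packaged study data: the KWZ extraction-optimization experiment.

KWZ (Kursi Wufarikun Ziyabit) is a two-plant antidiabetic prescription
(Geranium collinum root : Hypericum scabrum aerial parts, 7:3) whose
reflux-extraction conditions were optimized on a four-factor Box-Behnken
design: ethanol concentration (30/50/70 %), temperature (60/70/80 degC),
solvent-to-solid ratio (10/20/30 mL/g) and time (2/3/4 h).  The 29-run
design carries five measured responses -- extraction yield, total
polyphenol content, PTP-1B inhibition, alpha-glucosidase inhibition and
ABTS inhibition (all percent) -- plus a DPPH scavenging column that was
measured but never modelled.  The UPLC side ships the 12-component
system-suitability RSDs, calibration regressions, contents and linear
ranges, and the study's reported per-response optima.

All loaders read small CSV/YAML files shipped inside the package; the
design table stores natural factor values, and coded settings are
recomputed from the level specifications (the published coded labels
contain typos while the natural values are internally consistent).
"""

from __future__ import annotations

from importlib import resources

import pandas as pd
import yaml

from .factors import DesignTable, FactorSpec

__all__ = [
    "load_factors",
    "load_design",
    "load_predicted_optima",
    "load_suitability",
    "load_components",
    "load_dpph",
    "RESPONSE_NAMES",
]

#: Modelled response columns of the packaged design table.
RESPONSE_NAMES = ["yield", "tpc", "ptp1b", "aglu", "abts"]

#: Row ids of the five replicated center runs in the packaged design.
CENTER_RUN_IDS = [7, 13, 20, 24, 28]


def _data(name: str):
    return resources.files("rsmextract.data").joinpath(name)


def load_factors(path=None) -> list[FactorSpec]:
    """Factor specifications (from a YAML file; default: packaged KWZ set)."""
    src = _data("kwz_factors.yaml") if path is None else path
    with open(src) as fh:
        doc = yaml.safe_load(fh)
    return [
        FactorSpec(
            name=f["name"], unit=f.get("unit", ""),
            low=float(f["low"]), center=float(f["center"]), high=float(f["high"]),
        )
        for f in doc["factors"]
    ]


def load_design() -> tuple[DesignTable, pd.DataFrame]:
    """The 29-run KWZ design with its response columns.

    Returns ``(DesignTable, DataFrame)``; the frame holds ``run_id`` plus
    the five response columns in :data:`RESPONSE_NAMES`.
    """
    factors = load_factors()
    df = pd.read_csv(_data("kwz_design.csv"))
    design = DesignTable.from_natural(factors, df)
    return design, df[["run_id", *RESPONSE_NAMES]].copy()


def load_predicted_optima() -> pd.DataFrame:
    """The study's reported single-response optima (natural units)."""
    return pd.read_csv(_data("kwz_predicted_optima.csv"))


def load_suitability() -> pd.DataFrame:
    """Published per-peak RSDs of RRT/RPA for precision, stability and
    repeatability (percent; reference peak 5 rows are zero)."""
    return pd.read_csv(_data("kwz_suitability.csv"))


def load_components() -> pd.DataFrame:
    """The 12 identified components: retention time, calibration line
    (slope/intercept/R^2), percent content and linear range."""
    return pd.read_csv(_data("kwz_components.csv"))


def load_dpph() -> pd.DataFrame:
    """DPPH scavenging rates (mean +/- sd, percent) of the 29 runs."""
    return pd.read_csv(_data("kwz_dpph.csv"))
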