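"""Experimental factors and Box-Behnken designs.

A factor is described by its natural low/center/high levels; the linear
coding map sends them to -1/0/+1.  A Box-Behnken design (BBD) for ``k``
factors consists of the four (+/-1, +/-1) sign combinations on every
unordered factor pair -- with all remaining factors held at the center --
plus ``n_center`` replicated all-zero center runs, giving
``2*k*(k-1) + n_center`` runs in total.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FactorSpec",
    "DesignTable",
    "make_bbd",
    "code_value",
    "decode_value",
]


@dataclass(frozen=True)
class FactorSpec:
    """One experimental factor with its coded <-> natural linear map.

    Parameters
    ----------
    name : str
        Short label, e.g. ``"ethanol"``.
    low, center, high : float
        Natural-unit levels mapped to coded -1, 0, +1.  ``center`` must
        be the midpoint of ``low`` and ``high`` for the map to be linear
        and consistent at all three anchors.
    unit : str, optional
        Free-text unit annotation.
    """

    name: str
    low: float
    center: float
    high: float
    unit: str = ""

    def __post_init__(self) -> None:
        if not (self.low < self.center < self.high):
            raise ValueError(
                f"factor {self.name!r}: levels must satisfy low < center < high, "
                f"got ({self.low}, {self.center}, {self.high})"
            )
        midpoint = 0.5 * (self.low + self.high)
        if abs(self.center - midpoint) > 1e-9 * (self.high - self.low):
            raise ValueError(
                f"factor {self.name!r}: center {self.center} is not the midpoint "
                f"of ({self.low}, {self.high}); the -1/0/+1 coding would be inconsistent"
            )

    @property
    def half_width(self) -> float:
        """Half the natural-unit span, the denominator of the coding map."""
        return 0.5 * (self.high - self.low)

    def code(self, natural):
        """Map natural units to coded units: ``(x - center) / half_width``."""
        coded = (np.asarray(natural, dtype=float) - self.center) / self.half_width
        if np.any(np.abs(coded) > 1 + 1e-9):
            warnings.warn(
                f"factor {self.name!r}: value outside the design range "
                f"[{self.low}, {self.high}] (extrapolation)",
                stacklevel=2,
            )
        return coded if coded.ndim else float(coded)

    def decode(self, coded):
        """Exact inverse of :meth:`code`."""
        natural = np.asarray(coded, dtype=float) * self.half_width + self.center
        return natural if natural.ndim else float(natural)


def code_value(spec: FactorSpec, natural):
    """Functional alias of :meth:`FactorSpec.code`."""
    return spec.code(natural)


def decode_value(spec: FactorSpec, coded):
    """Functional alias of :meth:`FactorSpec.decode`."""
    return spec.decode(coded)


@dataclass
class DesignTable:
    """A coded run matrix paired with its factor specifications.

    Attributes
    ----------
    factors : list of FactorSpec
        Ordered factor specifications (columns of ``coded``).
    run_ids : list
        One identifier per run, in row order.
    coded : ndarray, shape (n_runs, k)
        Coded settings; for a Box-Behnken design every entry is in
        {-1, 0, +1}.
    """

    factors: list[FactorSpec]
    run_ids: list
    coded: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.coded = np.asarray(self.coded, dtype=float)
        if self.coded.ndim != 2 or self.coded.shape[1] != len(self.factors):
            raise ValueError("coded matrix shape does not match the factor list")
        if len(self.run_ids) != self.coded.shape[0]:
            raise ValueError("run_ids length does not match the number of runs")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_runs(self) -> int:
        return self.coded.shape[0]

    @property
    def factor_names(self) -> list[str]:
        return [f.name for f in self.factors]

    @property
    def center_mask(self) -> np.ndarray:
        """Boolean mask of all-zero (center) runs."""
        return np.all(self.coded == 0.0, axis=1)

    @property
    def n_center(self) -> int:
        return int(self.center_mask.sum())

    def natural(self) -> np.ndarray:
        """Decode the run matrix back to natural units."""
        return np.column_stack(
            [f.decode(self.coded[:, j]) for j, f in enumerate(self.factors)]
        )

    def validate_bbd(self) -> None:
        """Check the Box-Behnken structural invariants; raise on violation.

        Entries must lie in {-1, 0, +1}; columns must sum to zero and be
        mutually orthogonal; the run count must equal
        ``2 k (k-1) + n_center``.
        """
        if not np.isin(self.coded, (-1.0, 0.0, 1.0)).all():
            raise ValueError("coded entries outside {-1, 0, +1}")
        sums = self.coded.sum(axis=0)
        if np.any(sums != 0):
            raise ValueError(f"coded columns do not sum to zero: {sums}")
        gram = self.coded.T @ self.coded
        off = gram - np.diag(np.diag(gram))
        if np.any(off != 0):
            raise ValueError("coded columns are not orthogonal")
        expected = 2 * self.k * (self.k - 1) + self.n_center
        if self.n_runs != expected:
            raise ValueError(
                f"run count {self.n_runs} != 2k(k-1) + n_center = {expected}"
            )

    def to_frame(self, include_coded: bool = False) -> pd.DataFrame:
        """Tabulate the design in natural units (optionally with coded columns)."""
        df = pd.DataFrame(self.natural(), columns=self.factor_names)
        df.insert(0, "run_id", self.run_ids)
        if include_coded:
            for j, name in enumerate(self.factor_names):
                df[f"{name}_coded"] = self.coded[:, j]
        return df

    def to_csv(self, path, include_coded: bool = False) -> None:
        self.to_frame(include_coded=include_coded).to_csv(path, index=False)

    @classmethod
    def from_natural(cls, factors: list[FactorSpec], df: pd.DataFrame) -> "DesignTable":
        """Build a design table by coding natural-unit factor columns.

        ``df`` must contain one column per factor name and, optionally, a
        ``run_id`` column (row numbers are used otherwise).
        """
        missing = [f.name for f in factors if f.name not in df.columns]
        if missing:
            raise ValueError(f"missing factor columns: {missing}")
        coded = np.column_stack([f.code(df[f.name].to_numpy()) for f in factors])
        # snap floating-point coding noise onto exact design levels
        coded = np.where(np.isclose(coded, np.round(coded), atol=1e-9), np.round(coded) + 0.0, coded)
        if "run_id" in df.columns:
            run_ids = list(df["run_id"])
        else:
            run_ids = list(range(1, len(df) + 1))
        return cls(factors=list(factors), run_ids=run_ids, coded=coded)


def make_bbd(
    factors: list[FactorSpec], n_center: int, seed: int | None = None
) -> DesignTable:
    """Construct a Box-Behnken design.

    Edge runs enumerate factor pairs in lexicographic order, each with the
    sign combinations (-1,-1), (-1,+1), (+1,-1), (+1,+1); ``n_center``
    all-zero runs follow.  Run order is deterministic unless ``seed`` is
    given, in which case rows are shuffled reproducibly.
    """
    k = len(factors)
    if not 3 <= k <= 7:
        raise ValueError(f"Box-Behnken designs require 3..7 factors, got {k}")
    names = [f.name for f in factors]
    if len(set(names)) != k:
        raise ValueError(f"duplicate factor names: {names}")
    if n_center < 1:
        raise ValueError("n_center must be >= 1")

    rows = []
    for i, j in itertools.combinations(range(k), 2):
        for si, sj in ((-1, -1), (-1, 1), (1, -1), (1, 1)):
            row = np.zeros(k)
            row[i], row[j] = si, sj
            rows.append(row)
    rows.extend(np.zeros(k) for _ in range(n_center))
    coded = np.asarray(rows)
    if seed is not None:
        order = np.random.default_rng(seed).permutation(len(rows))
        coded = coded[order]
    return DesignTable(
        factors=list(factors), run_ids=list(range(1, len(rows) + 1)), coded=coded
    )
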