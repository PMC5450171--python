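"""Second-order response-surface regression with lack-of-fit ANOVA.

The response model is the full quadratic polynomial in coded units,

    Y = b0 + sum_i b_i X_i + sum_i b_ii X_i^2 + sum_{i<j} b_ij X_i X_j ,

fit by ordinary least squares.  No term dropping is performed: the model
always carries all ``k(k+3)/2 + 1`` coefficients.  The ANOVA partitions
the residual sum of squares into pure error (variation among replicated
runs, here the center points) and lack of fit, and tests both the overall
regression and the adequacy of the quadratic form by F ratios.

OLS estimation is delegated to :mod:`statsmodels`; the design-specific
bookkeeping (term construction, replicate grouping, lack-of-fit
partition) is done here.
"""

from __future__ import annotations

import itertools
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .factors import DesignTable, FactorSpec

__all__ = [
    "QuadraticModel",
    "AnovaRow",
    "AnovaTable",
    "FitResult",
    "build_model_matrix",
    "fit_quadratic",
    "anova",
    "influence_ranking",
    "InfluenceRanking",
]


def _term_names(names: list[str]) -> list[str]:
    k = len(names)
    terms = ["Intercept"]
    terms += names
    terms += [f"{names[i]}:{names[j]}" for i, j in itertools.combinations(range(k), 2)]
    terms += [f"{n}^2" for n in names]
    return terms


def build_model_matrix(coded: np.ndarray, names: list[str]):
    """Full second-order model matrix for a coded run matrix.

    Column order: intercept, linear terms, pairwise interactions
    (lexicographic), pure quadratics.  Returns ``(matrix, term_names)``.
    """
    coded = np.asarray(coded, dtype=float)
    n, k = coded.shape
    cols = [np.ones(n)]
    cols += [coded[:, i] for i in range(k)]
    cols += [coded[:, i] * coded[:, j] for i, j in itertools.combinations(range(k), 2)]
    cols += [coded[:, i] ** 2 for i in range(k)]
    return np.column_stack(cols), _term_names(list(names))


@dataclass
class QuadraticModel:
    """A fitted (or postulated) full second-order polynomial in coded units."""

    response_name: str
    factors: list[FactorSpec]
    intercept: float
    linear: np.ndarray  # (k,)
    interaction: np.ndarray  # (k, k) upper-triangular, b_ij at [i, j], i < j
    quadratic: np.ndarray  # (k,)

    def __post_init__(self) -> None:
        k = len(self.factors)
        self.linear = np.asarray(self.linear, dtype=float)
        self.quadratic = np.asarray(self.quadratic, dtype=float)
        self.interaction = np.asarray(self.interaction, dtype=float)
        if self.linear.shape != (k,) or self.quadratic.shape != (k,):
            raise ValueError("coefficient counts do not match the number of factors")
        if self.interaction.shape != (k, k):
            raise ValueError("interaction matrix must be k x k")
        if np.any(np.tril(self.interaction) != 0):
            raise ValueError("interaction matrix must be strictly upper-triangular")

    @property
    def k(self) -> int:
        return len(self.factors)

    @property
    def n_terms(self) -> int:
        """Number of coefficients including the intercept."""
        return 1 + self.k * (self.k + 3) // 2

    @property
    def term_names(self) -> list[str]:
        return _term_names([f.name for f in self.factors])

    @property
    def coef_vector(self) -> np.ndarray:
        """Coefficients in model-matrix column order."""
        pairs = [self.interaction[i, j] for i, j in itertools.combinations(range(self.k), 2)]
        return np.concatenate(([self.intercept], self.linear, pairs, self.quadratic))

    def predict(self, coded_points) -> np.ndarray | float:
        """Evaluate the polynomial at one coded point or a stack of points."""
        pts = np.atleast_2d(np.asarray(coded_points, dtype=float))
        if pts.shape[1] != self.k:
            raise ValueError(f"points must have {self.k} coordinates")
        m, _ = build_model_matrix(pts, [f.name for f in self.factors])
        out = m @ self.coef_vector
        return float(out[0]) if np.asarray(coded_points).ndim == 1 else out

    def hessian(self) -> np.ndarray:
        """Hessian of the surface: 2*diag(b_ii) with b_ij off-diagonal."""
        h = self.interaction + self.interaction.T
        h[np.diag_indices(self.k)] = 2.0 * self.quadratic
        return h

    def gradient_at(self, coded_point) -> np.ndarray:
        x = np.asarray(coded_point, dtype=float)
        return self.linear + self.hessian() @ x

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "factors": [
                {"name": f.name, "unit": f.unit, "low": f.low, "center": f.center, "high": f.high}
                for f in self.factors
            ],
            "intercept": self.intercept,
            "linear": self.linear.tolist(),
            "interaction": self.interaction.tolist(),
            "quadratic": self.quadratic.tolist(),
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "QuadraticModel":
        return cls(
            response_name=d["response_name"],
            factors=[FactorSpec(**f) for f in d["factors"]],
            intercept=float(d["intercept"]),
            linear=np.asarray(d["linear"], dtype=float),
            interaction=np.asarray(d["interaction"], dtype=float),
            quadratic=np.asarray(d["quadratic"], dtype=float),
        )

    @classmethod
    def from_json(cls, path) -> "QuadraticModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    @classmethod
    def from_coef_vector(
        cls, response_name: str, factors: list[FactorSpec], coefs
    ) -> "QuadraticModel":
        """Inverse of :attr:`coef_vector` (model-matrix column order)."""
        k = len(factors)
        coefs = np.asarray(coefs, dtype=float)
        n_pairs = k * (k - 1) // 2
        if coefs.shape != (1 + 2 * k + n_pairs,):
            raise ValueError("coefficient vector length does not match k")
        inter = np.zeros((k, k))
        for (i, j), b in zip(itertools.combinations(range(k), 2), coefs[1 + k : 1 + k + n_pairs]):
            inter[i, j] = b
        return cls(
            response_name=response_name,
            factors=list(factors),
            intercept=float(coefs[0]),
            linear=coefs[1 : 1 + k],
            interaction=inter,
            quadratic=coefs[1 + k + n_pairs :],
        )


@dataclass(frozen=True)
class AnovaRow:
    ss: float
    df: int
    ms: float | None = None
    f: float | None = None
    p: float | None = None


@dataclass
class AnovaTable:
    """ANOVA of a quadratic response-surface fit.

    Rows: ``model``, ``residual``, ``pure_error``, ``lack_of_fit``,
    ``total`` (the replicate-based rows are absent when the design holds
    no replicated runs).  Also carries R^2 and adjusted R^2.
    """

    response_name: str
    rows: dict[str, AnovaRow]
    r_squared: float
    adj_r_squared: float

    def to_frame(self) -> pd.DataFrame:
        order = [k for k in ("model", "residual", "pure_error", "lack_of_fit", "total") if k in self.rows]
        recs = [
            {"source": k, "ss": self.rows[k].ss, "df": self.rows[k].df,
             "ms": self.rows[k].ms, "F": self.rows[k].f, "p": self.rows[k].p}
            for k in order
        ]
        return pd.DataFrame(recs)

    def to_markdown(self) -> str:
        """Human-readable ANOVA report (coefficient precision matches the
        conventional RSM reporting style: SS/MS/F to 2 dp, R^2 to 4 dp)."""
        lines = [
            f"### ANOVA: {self.response_name}",
            "",
            "| Source | Sum of squares | df | Mean square | F | p |",
            "|---|---|---|---|---|---|",
        ]
        for rec in self.to_frame().to_dict("records"):
            ms = "" if rec["ms"] is None else f"{rec['ms']:.2f}"
            f = "" if rec["F"] is None else f"{rec['F']:.2f}"
            p = "" if rec["p"] is None else f"{rec['p']:.4f}"
            lines.append(f"| {rec['source']} | {rec['ss']:.2f} | {rec['df']} | {ms} | {f} | {p} |")
        lines += ["", f"R² = {self.r_squared:.4f}, adjusted R² = {self.adj_r_squared:.4f}"]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "response_name": self.response_name,
            "rows": {k: vars(v) for k, v in self.rows.items()},
            "r_squared": self.r_squared,
            "adj_r_squared": self.adj_r_squared,
        }


@dataclass
class FitResult:
    """Bundle of a fitted :class:`QuadraticModel` with its inference.

    ``coef_table`` holds per-term estimate, standard error, t statistic,
    two-sided p value (residual df) and a significance flag at ``alpha``.
    """

    model: QuadraticModel
    coef_table: pd.DataFrame
    fitted: np.ndarray
    residuals: np.ndarray
    alpha: float

    @property
    def significant_terms(self) -> list[str]:
        tbl = self.coef_table
        return list(tbl.loc[tbl["significant"] & (tbl["term"] != "Intercept"), "term"])


def fit_quadratic(
    design: DesignTable, response, response_name: str | None = None, alpha: float = 0.05
) -> FitResult:
    """Fit the full second-order polynomial to one response by OLS.

    ``response`` is a length-``n`` vector aligned with the design's runs
    (a named pandas Series supplies ``response_name``).  Standard errors
    come from the unscaled covariance matrix times the residual mean
    square; p values are two-sided t on residual degrees of freedom.
    """
    if isinstance(response, pd.Series) and response_name is None:
        response_name = str(response.name)
    y = np.asarray(response, dtype=float)
    if y.shape != (design.n_runs,):
        raise ValueError(
            f"response length {y.size} does not match the design's {design.n_runs} runs"
        )
    m, terms = build_model_matrix(design.coded, design.factor_names)
    p = m.shape[1]
    if design.n_runs <= p:
        raise ValueError(f"need more than {p} runs to fit {p} terms, got {design.n_runs}")
    if np.linalg.matrix_rank(m) < p:
        raise ValueError("model matrix is rank-deficient; design cannot support a full quadratic")
    res = sm.OLS(y, m).fit()
    model = QuadraticModel.from_coef_vector(response_name or "response", design.factors, res.params)
    coef_table = pd.DataFrame(
        {
            "term": terms,
            "estimate": res.params,
            "se": res.bse,
            "t": res.tvalues,
            "p": res.pvalues,
        }
    )
    coef_table["significant"] = coef_table["p"] < alpha
    return FitResult(
        model=model,
        coef_table=coef_table,
        fitted=np.asarray(res.fittedvalues),
        residuals=np.asarray(res.resid),
        alpha=alpha,
    )


def _replicate_groups(coded: np.ndarray) -> list[np.ndarray]:
    """Indices of runs sharing identical coded settings (size >= 2)."""
    seen: dict[tuple, list[int]] = {}
    for idx, row in enumerate(coded):
        seen.setdefault(tuple(row), []).append(idx)
    return [np.asarray(ix) for ix in seen.values() if len(ix) >= 2]


def anova(model: QuadraticModel, design: DesignTable, response) -> AnovaTable:
    """ANOVA table with the pure-error / lack-of-fit partition.

    Pure error pools squared deviations from the group mean over every
    set of replicated runs (for a BBD, the center points); lack of fit is
    the residual remainder.  When the design has no replicates the two
    rows are omitted with a warning.
    """
    y = np.asarray(response, dtype=float)
    yhat = model.predict(design.coded)
    n = y.size
    p = model.n_terms - 1  # non-intercept terms
    ybar = y.mean()

    ss_model = float(np.sum((yhat - ybar) ** 2))
    ss_res = float(np.sum((y - yhat) ** 2))
    ss_tot = float(np.sum((y - ybar) ** 2))
    df_model, df_res = p, n - p - 1
    ms_model, ms_res = ss_model / df_model, ss_res / df_res
    f_model = ms_model / ms_res
    p_model = float(stats.f.sf(f_model, df_model, df_res))

    r2 = ss_model / ss_tot
    adj = 1.0 - (1.0 - r2) * (n - 1) / df_res

    rows = {
        "model": AnovaRow(ss_model, df_model, ms_model, f_model, p_model),
        "residual": AnovaRow(ss_res, df_res, ms_res),
    }

    groups = _replicate_groups(design.coded)
    if not groups:
        warnings.warn(
            "design has no replicated runs: pure error and lack of fit are undefined",
            stacklevel=2,
        )
    else:
        ss_pe = float(sum(np.sum((y[g] - y[g].mean()) ** 2) for g in groups))
        df_pe = int(sum(len(g) - 1 for g in groups))
        ss_lof = ss_res - ss_pe
        df_lof = df_res - df_pe
        rows["pure_error"] = AnovaRow(ss_pe, df_pe, ss_pe / df_pe)
        if df_lof > 0:
            ms_lof = ss_lof / df_lof
            if ss_pe > 0:
                f_lof = ms_lof / (ss_pe / df_pe)
                rows["lack_of_fit"] = AnovaRow(
                    ss_lof, df_lof, ms_lof, f_lof, float(stats.f.sf(f_lof, df_lof, df_pe))
                )
            else:
                # exact replicates (e.g. noiseless data): F ratio undefined
                rows["lack_of_fit"] = AnovaRow(ss_lof, df_lof, ms_lof)
    rows["total"] = AnovaRow(ss_tot, n - 1)
    return AnovaTable(
        response_name=model.response_name, rows=rows, r_squared=r2, adj_r_squared=adj
    )


@dataclass(frozen=True)
class InfluenceRanking:
    """Factors ordered by decreasing |coded linear coefficient|."""

    order: list[str]
    tied: bool


def influence_ranking(model: QuadraticModel) -> InfluenceRanking:
    """Rank factors by the absolute value of their coded linear effect.

    Ties keep factor order and set the ``tied`` flag (also warned).
    """
    mags = np.abs(model.linear)
    # stable sort preserves input order among ties
    order = list(np.argsort(-mags, kind="stable"))
    tied = bool(len(np.unique(mags)) < len(mags))
    if tied:
        warnings.warn("tied linear-effect magnitudes; ranking is order-dependent", stacklevel=2)
    names = [model.factors[i].name for i in order]
    return InfluenceRanking(order=names, tied=tied)
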