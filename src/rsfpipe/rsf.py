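"""Seasonal resource-selection models over used/available tables.

Wraps the adaptive-quadrature random-intercept fitter with the design
table interface, collinearity screening (VIF), Wald inference, and AIC
competition across land-cover aggregation hypotheses.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .design import AggregationScheme, UseAvailableTable, build_design_tables
from .mixedlogit import MixedLogitResult, fit_mixed_logit

__all__ = [
    "FittedRSF",
    "ModelRanking",
    "fit_random_intercept_logit",
    "variance_inflation",
    "wald_summary",
    "compete_aggregations",
]


@dataclass
class FittedRSF:
    """A fitted per-season resource-selection model."""

    season: str
    scheme: str
    beta0: float
    beta: dict[str, float]  # predictor -> coefficient (excludes intercept)
    sigma_b: float
    se: dict[str, float]  # includes "(Intercept)"
    loglik: float
    aic: float
    n_obs: int
    n_groups: int
    converged: bool
    boundary: bool
    standardization: dict[str, float]
    reference_category: str = ""
    raw: MixedLogitResult | None = None

    def coefficient(self, name: str) -> float:
        if name == "(Intercept)":
            return self.beta0
        return self.beta[name]

    def to_json(self) -> str:
        d = {
            "season": self.season, "scheme": self.scheme, "beta0": self.beta0,
            "beta": self.beta, "sigma_b": self.sigma_b, "se": self.se,
            "loglik": self.loglik, "aic": self.aic, "n_obs": self.n_obs,
            "n_groups": self.n_groups, "converged": self.converged,
            "boundary": self.boundary, "standardization": self.standardization,
            "reference_category": self.reference_category,
        }
        return json.dumps(d, indent=1)

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json())

    @classmethod
    def read(cls, path: str | Path) -> "FittedRSF":
        d = json.loads(Path(path).read_text())
        return cls(raw=None, **d)


def fit_random_intercept_logit(
    table: UseAvailableTable, season: str, n_nodes: int = 15
) -> FittedRSF:
    """Fit the season's random-intercept logistic model from a design table.

    Predictors are the non-reference category proportions plus the
    standardized linear and centered-quadratic distance-to-flowline terms;
    the individual enters as a Gaussian random intercept.
    """
    sub = table.season_frame(season)
    if sub.empty:
        raise ValueError(f"no rows for season {season!r}")
    groups = sub["individual_id"].to_numpy()
    if len(np.unique(groups)) < 2:
        raise ValueError("need >= 2 individuals (groups) to fit a random intercept")
    cols = table.predictor_columns
    X = np.column_stack([np.ones(len(sub))] + [sub[c].to_numpy() for c in cols])
    names = ["(Intercept)"] + cols
    res = fit_mixed_logit(X, sub["used"].to_numpy(float), groups, names=names, n_nodes=n_nodes)
    beta = dict(zip(cols, res.beta[1:]))
    se = dict(zip(names, res.se))
    return FittedRSF(
        season=season,
        scheme=table.scheme_name,
        beta0=float(res.beta[0]),
        beta={k: float(v) for k, v in beta.items()},
        sigma_b=float(res.sigma_b),
        se={k: float(v) for k, v in se.items()},
        loglik=float(res.loglik),
        aic=float(res.aic),
        n_obs=res.n_obs,
        n_groups=res.n_groups,
        converged=bool(res.converged),
        boundary=bool(res.boundary),
        standardization=table.standardization[season],
        reference_category=table.reference_category,
        raw=res,
    )


def variance_inflation(
    table: UseAvailableTable | pd.DataFrame,
    season: str | None = None,
    columns: list[str] | None = None,
) -> dict[str, float]:
    """VIF_k = 1 / (1 - R^2_k) from regressing predictor k on the others.

    Ordinary least squares on the design (with intercept), ignoring the
    response.  Exact collinearity yields an infinite VIF with a warning;
    any VIF >= 3 triggers a collinearity warning.  Accepts either a
    design table (predictor set implied) or a plain frame plus columns.
    """
    if isinstance(table, pd.DataFrame):
        df = table
        cols = columns if columns is not None else list(df.columns)
    else:
        df = table.df if season is None else table.season_frame(season)
        cols = columns if columns is not None else table.predictor_columns
    if len(cols) < 2:
        raise ValueError("VIF needs at least 2 predictors")
    Z = df[cols].to_numpy(float)
    out: dict[str, float] = {}
    for k, name in enumerate(cols):
        yk = Z[:, k]
        Xk = np.column_stack([np.ones(len(Z)), np.delete(Z, k, axis=1)])
        coef, _, _, _ = np.linalg.lstsq(Xk, yk, rcond=None)
        resid = yk - Xk @ coef
        tss = np.sum((yk - yk.mean()) ** 2)
        rss = float(np.sum(resid**2))
        if tss <= 0 or rss / tss < 1e-12:
            warnings.warn(f"predictor {name} is exactly collinear (rank deficiency)")
            out[name] = np.inf
            continue
        r2 = 1.0 - rss / tss
        out[name] = float(1.0 / (1.0 - r2))
        if out[name] >= 3:
            warnings.warn(f"VIF for {name} is {out[name]:.2f} (>= 3)")
    return out


def wald_summary(model: FittedRSF, alpha: float = 0.05) -> pd.DataFrame:
    """Per-coefficient Wald tests and (1 - alpha) confidence intervals.

    A coefficient whose interval covers zero is reported ``neutral``; a
    missing standard error marks the row not-assessable.
    """
    zq = stats.norm.ppf(1.0 - alpha / 2.0)
    rows = []
    for name in ["(Intercept)"] + list(model.beta):
        est = model.coefficient(name)
        se = model.se.get(name, np.nan)
        if not np.isfinite(se) or se <= 0:
            rows.append((name, est, np.nan, np.nan, np.nan, np.nan, np.nan, "not-assessable"))
            continue
        z = est / se
        p = 2.0 * stats.norm.sf(abs(z))
        lo, hi = est - zq * se, est + zq * se
        verdict = "neutral" if lo <= 0.0 <= hi else "significant"
        rows.append((name, est, se, z, p, lo, hi, verdict))
    return pd.DataFrame(
        rows, columns=["term", "estimate", "se", "z", "p", "ci_lo", "ci_hi", "verdict"]
    )


@dataclass
class ModelRanking:
    """AIC-sorted competition result across aggregation hypotheses."""

    season: str
    table: pd.DataFrame  # scheme, aic, delta_aic, loglik, k (sorted by aic)
    decisive: bool  # runner-up delta AIC >= 2
    excluded: list[str] = field(default_factory=list)

    @property
    def winner(self) -> str:
        return str(self.table.iloc[0]["scheme"])


def compete_aggregations(
    tables: dict[str, UseAvailableTable],
    season: str,
    n_nodes: int = 15,
    delta_decisive: float = 2.0,
) -> tuple[ModelRanking, dict[str, FittedRSF]]:
    """Fit one model per aggregation scheme and rank by AIC.

    The tables must share the same underlying used/available point set
    (:func:`rsfpipe.design.build_design_tables` guarantees this), so only
    the land-cover aggregation differs between candidates.  Non-converged
    fits are excluded from the ranking with a notice.
    """
    fits: dict[str, FittedRSF] = {}
    excluded: list[str] = []
    for name, table in tables.items():
        fit = fit_random_intercept_logit(table, season, n_nodes=n_nodes)
        fits[name] = fit
        if not fit.converged:
            excluded.append(name)
            warnings.warn(f"scheme {name} did not converge; excluded from ranking")
    rows = [
        {
            "scheme": name,
            "aic": fit.aic,
            "loglik": fit.loglik,
            "k": len(fit.beta) + 2,  # fixed effects + intercept + variance
        }
        for name, fit in fits.items()
        if name not in excluded
    ]
    if not rows:
        raise ValueError("no converged fits to rank")
    df = pd.DataFrame(rows).sort_values("aic", kind="mergesort", ignore_index=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    df = df[["scheme", "aic", "delta_aic", "loglik", "k"]]
    decisive = len(df) > 1 and bool(df["delta_aic"].iloc[1] >= delta_decisive)
    return ModelRanking(season, df, decisive, excluded), fits
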