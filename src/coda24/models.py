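"""Covariate-adjusted linear models of wellbeing on ILR coordinates.

For each wellbeing domain the outcome is regressed on the three pivot ILR
coordinates of the 4-part time-use composition, adjusted for age and gender,
with school-cluster-robust (CR1 sandwich) standard errors referenced to a
t distribution with G-1 degrees of freedom (G = number of schools). The
"rotation" device refits the identical model once per behaviour with that
behaviour as the ILR pivot: the fitted values, residuals, R^2 and the joint
model test are invariant (the ILR block changes by an orthogonal map), and
only the first coordinate's coefficient — behaviour vs the geometric mean of
the rest — is read off each fit.

Point estimates are ordinary least squares (statsmodels OLS). Naive OLS and
cluster-robust standard errors are both retained; cluster-robust is the
default for inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .coda import CANONICAL_PARTS, IlrBasis, ilr_transform, rotate_basis
__all__ = [
    "ModelSpec",
    "FittedCompositionModel",
    "fit_model",
    "fit_rotations",
    "model_diagnostics",
    "rotation_table",
]

ILR_NAMES = ("z1", "z2", "z3")


@dataclass(frozen=True)
class ModelSpec:
    """What to fit: outcome, pivot basis, covariates and clustering."""

    outcome: str
    basis: IlrBasis
    covariates: tuple[str, ...] = ("age", "gender")
    cluster: str = "school"
    alpha: float = 0.05
    parts: tuple[str, ...] = CANONICAL_PARTS


@dataclass(frozen=True)
class FittedCompositionModel:
    """A fitted rotation with both naive and cluster-robust inference."""

    spec: ModelSpec
    params: pd.Series
    cov_cluster: pd.DataFrame
    cov_ols: pd.DataFrame
    bse: pd.Series  # cluster-robust SEs (the default inference)
    bse_ols: pd.Series
    pvalues: pd.Series  # t(G-1) two-sided, cluster-robust
    r_squared: float
    model_p: float  # joint Wald test of all non-intercept terms
    n_used: int
    n_clusters: int
    df_inference: int  # G - 1
    fittedvalues: np.ndarray = field(repr=False, default=None)
    resid: np.ndarray = field(repr=False, default=None)
    exog: pd.DataFrame = field(repr=False, default=None)
    n_dropped_gender: int = 0

    @property
    def pivot_label(self) -> str:
        rest = " + ".join(
            p.upper() if p != "sleep" else "Sleep"
            for p in self.spec.basis.pivot_order[1:]
        )
        pivot = self.spec.basis.pivot
        pivot = pivot.upper() if pivot != "sleep" else "Sleep"
        return f"{pivot} vs. ({rest})"

    def conf_int(self, name: str, level: float = 0.95) -> tuple[float, float]:
        tcrit = stats.t.ppf(0.5 + level / 2, self.df_inference)
        b, se = self.params[name], self.bse[name]
        return float(b - tcrit * se), float(b + tcrit * se)

    def ilr_beta(self) -> np.ndarray:
        return self.params[list(ILR_NAMES)].to_numpy(float)

    def ilr_cov(self) -> np.ndarray:
        return self.cov_cluster.loc[list(ILR_NAMES), list(ILR_NAMES)].to_numpy(float)


def _design(data: pd.DataFrame, spec: ModelSpec) -> tuple[pd.DataFrame, pd.Series, pd.Series, int]:
    """Build the design matrix; drops non-binary-gender and incomplete rows."""
    needed = [spec.outcome, *spec.parts, spec.cluster, *spec.covariates]
    missing = set(needed) - set(data.columns)
    if missing:
        raise ValueError(f"data is missing columns: {sorted(missing)}")
    df = data.dropna(subset=needed).copy()
    n_dropped_gender = 0
    if "gender" in spec.covariates:
        keep = df["gender"].isin(["male", "female"])
        n_dropped_gender = int((~keep).sum())
        df = df[keep]
    levels = df["gender"].nunique() if "gender" in spec.covariates else 2
    if "gender" in spec.covariates and levels < 2:
        raise ValueError("gender has a single level after exclusions; cannot adjust")
    if df[spec.cluster].nunique() < 2:
        raise ValueError("need at least 2 clusters for school adjustment")

    Z = ilr_transform(df[list(spec.parts)].to_numpy(float), spec.parts, spec.basis)
    X = pd.DataFrame(Z, columns=list(ILR_NAMES), index=df.index)
    for cov in spec.covariates:
        if cov == "gender":
            X["gender_female"] = (df["gender"] == "female").astype(float)
        else:
            X[cov] = df[cov].astype(float)
    X = sm.add_constant(X, prepend=True)
    rank = np.linalg.matrix_rank(X.to_numpy())
    if rank < X.shape[1]:
        corr = X.drop(columns="const").corr().abs()
        np.fill_diagonal(corr.values, 0)
        worst = corr.stack().idxmax()
        raise ValueError(f"design matrix is rank deficient (collinear columns, e.g. {worst})")
    if len(df) < X.shape[1] + 2:
        raise ValueError(
            f"too few complete cases ({len(df)}) for {X.shape[1]} parameters"
        )
    return X, df[spec.outcome].astype(float), df[spec.cluster], n_dropped_gender


def fit_model(data: pd.DataFrame, spec: ModelSpec) -> FittedCompositionModel:
    """OLS fit of one rotation with cluster-robust (CR1, t(G-1)) inference."""
    X, y, groups, n_dropped = _design(data, spec)
    ols = sm.OLS(y, X).fit()
    G = groups.nunique()
    res = sm.OLS(y, X).fit(
        cov_type="cluster",
        cov_kwds={"groups": groups, "use_correction": True},
        use_t=True,
    )
    k = X.shape[1]
    # Joint Wald test of every non-intercept coefficient, cluster-robust.
    R = np.eye(k)[1:]
    wald = res.wald_test(R, use_f=True, scalar=True)
    return FittedCompositionModel(
        spec=spec,
        params=res.params,
        cov_cluster=pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        cov_ols=pd.DataFrame(ols.cov_params(), index=X.columns, columns=X.columns),
        bse=res.bse,
        bse_ols=ols.bse,
        pvalues=res.pvalues,
        r_squared=float(res.rsquared),
        model_p=float(wald.pvalue),
        n_used=int(res.nobs),
        n_clusters=int(G),
        df_inference=int(G - 1),
        fittedvalues=np.asarray(res.fittedvalues),
        resid=np.asarray(res.resid),
        exog=X,
        n_dropped_gender=n_dropped,
    )


def fit_rotations(
    data: pd.DataFrame,
    outcome: str,
    parts: Sequence[str] = CANONICAL_PARTS,
    covariates: tuple[str, ...] = ("age", "gender"),
    cluster: str = "school",
    alpha: float = 0.05,
) -> dict[str, FittedCompositionModel]:
    """Fit the four pivot rotations of one outcome; keyed by pivot part."""
    parts = tuple(parts)
    out = {}
    for pivot in parts:
        spec = ModelSpec(
            outcome=outcome,
            basis=rotate_basis(parts, pivot),
            covariates=covariates,
            cluster=cluster,
            alpha=alpha,
            parts=parts,
        )
        out[pivot] = fit_model(data, spec)
    return out


def rotation_table(models: dict[str, FittedCompositionModel]) -> pd.DataFrame:
    """Summary rows per rotation: pivot-vs-rest beta, SE, p; shared R^2 / model p.

    One row per behaviour, mirroring the standard reporting layout for
    rotated pivot models.
    """
    rows = []
    for pivot, m in models.items():
        rows.append(
            {
                "outcome": m.spec.outcome,
                "pivot": pivot,
                "label": m.pivot_label,
                "beta": float(m.params["z1"]),
                "se": float(m.bse["z1"]),
                "p": float(m.pvalues["z1"]),
                "r_squared": m.r_squared,
                "model_p": m.model_p,
                "n": m.n_used,
            }
        )
    return pd.DataFrame(rows)


def variance_inflation_factors(X: pd.DataFrame) -> dict[str, float]:
    """VIF per non-constant column; ``inf`` marks perfect collinearity."""
    cols = [c for c in X.columns if c != "const"]
    out: dict[str, float] = {}
    for c in cols:
        others = sm.add_constant(X[[o for o in cols if o != c]], prepend=True)
        r2 = sm.OLS(X[c].to_numpy(float), others).fit().rsquared
        out[c] = float("inf") if r2 >= 1 - 1e-12 else float(1.0 / (1.0 - r2))
    return out


def model_diagnostics(
    model: FittedCompositionModel, extra_columns: pd.DataFrame | None = None
) -> dict:
    """Residual normality, heteroscedasticity and collinearity report.

    Shapiro-Wilk on the residuals, a Breusch-Pagan test of the residual
    variance against the design, and variance inflation factors for the
    design columns (``extra_columns`` lets callers probe candidate
    covariates). Report only — nothing is refitted.
    """
    from statsmodels.stats.diagnostic import het_breuschpagan

    resid = np.asarray(model.resid)
    shapiro_stat, shapiro_p = stats.shapiro(resid)
    bp_lm, bp_lm_p, _, _ = het_breuschpagan(resid, model.exog.to_numpy(float))
    X = model.exog
    if extra_columns is not None:
        X = pd.concat([X, extra_columns.set_axis(X.index)], axis=1)
    vif = variance_inflation_factors(X)
    return {
        "shapiro_stat": float(shapiro_stat),
        "shapiro_p": float(shapiro_p),
        "breusch_pagan_lm": float(bp_lm),
        "breusch_pagan_p": float(bp_lm_p),
        "normality_flag": bool(shapiro_p < model.spec.alpha),
        "heteroscedasticity_flag": bool(bp_lm_p < model.spec.alpha),
        "vif": vif,
        "vif_flagged": sorted(c for c, v in vif.items() if v > 10),
    }
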