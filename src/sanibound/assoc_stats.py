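"""Correlation screening, OLS, stepwise selection and validation.

The statistical core of the sanitary-boundary workflow: Pearson
correlation of the GWQI with hydrogeological covariates, ordinary
least squares with t-based stepwise variable selection (forward entry
at p < p_enter, backward removal at p > p_remove), variance inflation
factors for collinearity, a seeded train/validation split, and the
measured-vs-predicted validation R².

Model fitting is delegated to :mod:`statsmodels`; this module owns the
selection logic, the diagnostics surface and the report formats.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from .well_data import SchemaError, WellDataError, WellTable

__all__ = [
    "CorrelationMatrix",
    "RegressionFit",
    "SplitSpec",
    "ValidationReport",
    "correlation_matrix",
    "ols_fit",
    "stepwise_select",
    "vif",
    "split_train_validation",
    "validate_fit",
]

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class CorrelationMatrix:
    """Pairwise Pearson r with two-sided p-values (t transform)."""

    variables: tuple[str, ...]
    r: np.ndarray
    p: np.ndarray
    n: np.ndarray

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.variables.index(pair[0])
        j = self.variables.index(pair[1])
        return float(self.r[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.r, index=self.variables, columns=self.variables)

    def to_csv(self, path) -> None:
        df = self.to_dataframe()
        df.index.name = "variable"
        df.to_csv(path)


@dataclass(frozen=True)
class RegressionFit:
    """A fitted linear model for the GWQI response.

    Coefficients are carried at full precision; ``trace`` records the
    stepwise entry/removal history as ("add"|"drop", term, p) tuples.
    """

    response: str
    predictors: tuple[str, ...]
    intercept: float
    coefficients: dict[str, float]
    se: dict[str, float]        # keyed by term incl. "intercept"
    t: dict[str, float]
    p: dict[str, float]
    r_squared: float
    resid_std: float
    n: int
    trace: tuple = ()

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.predictors if c not in frame.columns]
        if missing:
            raise SchemaError(f"prediction input missing predictor(s): {missing}")
        y = np.full(len(frame), self.intercept, dtype=float)
        for name in self.predictors:
            y += self.coefficients[name] * frame[name].to_numpy(dtype=float)
        return y

    def summary_frame(self) -> pd.DataFrame:
        terms = ("intercept",) + self.predictors
        coef = {"intercept": self.intercept, **self.coefficients}
        return pd.DataFrame(
            {
                "term": terms,
                "coefficient": [coef[k] for k in terms],
                "se": [self.se.get(k, np.nan) for k in terms],
                "t": [self.t.get(k, np.nan) for k in terms],
                "p": [self.p.get(k, np.nan) for k in terms],
            }
        )

    def to_csv(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(f"# stepwise general linear model for {self.response}; "
                     f"r_squared={self.r_squared:.6g}\n")
            self.summary_frame().to_csv(fh, index=False)


@dataclass
class SplitSpec:
    """Seeded train/validation partition specification."""

    fraction: float = 0.8
    seed: int | None = None
    train_indices: tuple[int, ...] = ()
    validation_indices: tuple[int, ...] = ()

    def __post_init__(self):
        if not 0.0 < self.fraction < 1.0:
            raise WellDataError(
                f"split fraction must lie in (0, 1), got {self.fraction}"
            )


@dataclass(frozen=True)
class ValidationReport:
    """Measured vs predicted GWQI on held-out wells."""

    r_squared: float
    frame: pd.DataFrame  # columns: no, measured, predicted
    n: int


def _pearson_with_p(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    n = len(x)
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan, np.nan  # undefined for a constant variable
    r, _ = stats.pearsonr(x, y)
    # two-sided p from the t transform, t = r*sqrt((n-2)/(1-r^2))
    if abs(r) >= 1.0:
        return float(r), 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), n - 2)
    return float(r), float(p)


def correlation_matrix(wells: WellTable, variables: list[str]) -> CorrelationMatrix:
    """Pairwise-complete Pearson correlation among well-table columns.

    Constant variables yield NaN (undefined) entries, reported in the
    log rather than silently set to 0.
    """
    wells.require_columns(variables)
    k = len(variables)
    r = np.eye(k)
    p = np.zeros((k, k))
    n = np.zeros((k, k), dtype=int)
    frame = wells.frame
    for i in range(k):
        xi = frame[variables[i]]
        n[i, i] = int(xi.notna().sum())
        if np.ptp(xi.dropna().to_numpy()) == 0:
            r[i, i] = np.nan
            log.warning("correlation_matrix: %r is constant; r undefined",
                        variables[i])
    for i in range(k):
        for j in range(i + 1, k):
            sub = frame[[variables[i], variables[j]]].dropna()
            if len(sub) < 3:
                raise WellDataError(
                    f"need >= 3 complete rows for ({variables[i]}, "
                    f"{variables[j]}); have {len(sub)}"
                )
            if len(sub) < len(frame):
                log.info("pairwise-complete rows for (%s, %s): %d of %d",
                         variables[i], variables[j], len(sub), len(frame))
            rij, pij = _pearson_with_p(
                sub.iloc[:, 0].to_numpy(float), sub.iloc[:, 1].to_numpy(float)
            )
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
            n[i, j] = n[j, i] = len(sub)
    return CorrelationMatrix(tuple(variables), r, p, n)


def _design(wells: WellTable, response: str, predictors: list[str]):
    cols = [response] + list(predictors)
    wells.require_columns(cols)
    sub = wells.frame[cols].dropna()
    y = sub[response].to_numpy(dtype=float)
    X = sub[list(predictors)].to_numpy(dtype=float)
    return y, X, sub


def _name_collinear(X: np.ndarray, names: list[str]) -> list[str]:
    # columns whose removal restores full rank
    full = np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), X]))
    bad = []
    for j in range(X.shape[1]):
        Xr = np.delete(X, j, axis=1)
        if np.linalg.matrix_rank(np.column_stack([np.ones(len(X)), Xr])) == full:
            bad.append(names[j])
    return bad


def ols_fit(wells: WellTable, response: str, predictors: list[str],
            trace: tuple = ()) -> RegressionFit:
    """Ordinary least squares of ``response`` on ``predictors``.

    Standard errors use the unbiased residual variance; t = beta/SE with
    two-sided p-values.  A rank-deficient design raises and names the
    collinear columns.
    """
    y, X, _ = _design(wells, response, predictors)
    k = X.shape[1]
    if len(y) <= k + 1:
        raise WellDataError(
            f"need n > k+1 rows (n={len(y)}, k={k}) for OLS"
        )
    Xc = sm.add_constant(X, has_constant="add")
    if np.linalg.matrix_rank(Xc) < Xc.shape[1]:
        raise WellDataError(
            "singular design matrix; collinear columns: "
            f"{_name_collinear(X, list(predictors))}"
        )
    res = sm.OLS(y, Xc).fit()
    terms = ["intercept"] + list(predictors)
    return RegressionFit(
        response=response,
        predictors=tuple(predictors),
        intercept=float(res.params[0]),
        coefficients={p: float(b) for p, b in zip(predictors, res.params[1:])},
        se=dict(zip(terms, map(float, res.bse))),
        t=dict(zip(terms, map(float, res.tvalues))),
        p=dict(zip(terms, map(float, res.pvalues))),
        r_squared=float(res.rsquared),
        resid_std=float(np.sqrt(res.mse_resid)),
        n=int(res.nobs),
        trace=trace,
    )


def stepwise_select(
    wells: WellTable,
    response: str,
    candidates: list[str],
    p_enter: float = 0.05,
    p_remove: float = 0.10,
) -> RegressionFit:
    """t-based stepwise variable selection.

    Forward step: among excluded candidates, fit each added to the
    current model and enter the one with the smallest p-value if
    p < p_enter (ties broken by larger |t|, then candidate order).
    Backward step: drop the included predictor with the largest
    p > p_remove.  Iterate to a fixed point.  If nothing ever enters,
    the intercept-only fit is returned with a warning.
    """
    if not candidates:
        raise WellDataError("stepwise_select: no candidates")
    if p_enter > p_remove:
        raise WellDataError(
            f"p_enter ({p_enter}) must be <= p_remove ({p_remove})"
        )
    included: list[str] = []
    trace: list[tuple] = []
    while True:
        changed = False
        # forward; entry p-values are meaningless once the fit is exact
        best = None
        saturated = (
            included
            and 1.0 - ols_fit(wells, response, included).r_squared < 1e-12
        )
        for cand in candidates:
            if cand in included or saturated:
                continue
            fit = ols_fit(wells, response, included + [cand])
            pc, tc = fit.p[cand], abs(fit.t[cand])
            if pc < p_enter:
                key = (pc, -tc, candidates.index(cand))
                if best is None or key < best[0]:
                    best = (key, cand)
        if best is not None:
            included.append(best[1])
            trace.append(("add", best[1], best[0][0]))
            changed = True
        # backward
        while included:
            fit = ols_fit(wells, response, included)
            worst = max(included, key=lambda c: fit.p[c])
            if fit.p[worst] > p_remove:
                included.remove(worst)
                trace.append(("drop", worst, fit.p[worst]))
                changed = True
            else:
                break
        if not changed:
            break
    if not included:
        log.warning("stepwise_select: no candidate entered; "
                    "returning intercept-only fit")
        y, _, _ = _design(wells, response, candidates)
        return RegressionFit(
            response=response, predictors=(), intercept=float(np.mean(y)),
            coefficients={}, se={}, t={}, p={}, r_squared=0.0,
            resid_std=float(np.std(y, ddof=1)), n=len(y), trace=tuple(trace),
        )
    return ols_fit(wells, response, included, trace=tuple(trace))


def vif(wells: WellTable, predictors: list[str]) -> dict[str, float]:
    """Variance inflation factors, VIF_j = 1/(1 - R²_j).

    R²_j comes from regressing predictor j (with intercept) on the
    remaining predictors.  Perfect collinearity is reported as ``inf``.
    """
    if len(predictors) < 2:
        raise WellDataError("vif needs >= 2 predictors")
    _, X, sub = _design(wells, predictors[0], predictors[1:])
    frame = sub  # complete rows across all predictors
    out: dict[str, float] = {}
    for j, name in enumerate(predictors):
        others = [c for c in predictors if c != name]
        yj = frame[name].to_numpy(dtype=float)
        Xj = sm.add_constant(frame[others].to_numpy(dtype=float),
                             has_constant="add")
        res = sm.OLS(yj, Xj).fit()
        r2 = float(res.rsquared)
        if r2 >= 1.0 - 1e-12:
            out[name] = math.inf
            log.warning("vif: %r is perfectly collinear with %s", name, others)
        else:
            out[name] = 1.0 / (1.0 - r2)
    return out


def split_train_validation(
    wells: WellTable, spec: SplitSpec
) -> tuple[WellTable, WellTable]:
    """Seeded uniform random partition into train and validation tables.

    The training size is round(n * fraction) with half-away-from-zero
    rounding; the validation set is the complement.  The realized index
    sets are recorded on ``spec``.
    """
    n = len(wells)
    n_train = int(math.floor(n * spec.fraction + 0.5))
    rng = np.random.default_rng(spec.seed)
    perm = rng.permutation(n)
    train_idx = np.sort(perm[:n_train])
    valid_idx = np.sort(perm[n_train:])
    spec.train_indices = tuple(int(i) for i in train_idx)
    spec.validation_indices = tuple(int(i) for i in valid_idx)
    train = WellTable(wells.frame.iloc[train_idx].reset_index(drop=True),
                      wells.provenance)
    valid = WellTable(wells.frame.iloc[valid_idx].reset_index(drop=True),
                      wells.provenance)
    return train, valid


def validate_fit(
    fit: RegressionFit | None,
    validation: WellTable,
    use_stored_predictions: bool = False,
    about_identity: bool = False,
) -> ValidationReport:
    """Score predictions against measured GWQI on held-out wells.

    By default R² is the squared Pearson correlation between measured
    and predicted values; ``about_identity`` switches to
    1 - SSres/SStot about the y = x line.  With
    ``use_stored_predictions`` the table's ``gwqi_predicted`` column is
    scored instead of recomputing from ``fit``.
    """
    validation.require_columns(["gwqi_actual"])
    measured = validation.frame["gwqi_actual"].to_numpy(dtype=float)
    if use_stored_predictions:
        validation.require_columns(["gwqi_predicted"])
        predicted = validation.frame["gwqi_predicted"].to_numpy(dtype=float)
    else:
        if fit is None:
            raise WellDataError("validate_fit: need a fit or stored predictions")
        predicted = fit.predict(validation.frame)
    ok = ~(np.isnan(measured) | np.isnan(predicted))
    measured, predicted = measured[ok], predicted[ok]
    if about_identity:
        ss_res = float(np.sum((measured - predicted) ** 2))
        ss_tot = float(np.sum((measured - measured.mean()) ** 2))
        r2 = np.nan if ss_tot == 0 else 1.0 - ss_res / ss_tot
    else:
        if np.ptp(predicted) == 0 or np.ptp(measured) == 0:
            log.warning("validate_fit: constant measured or predicted values; "
                        "R² undefined")
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(measured, predicted)[0, 1] ** 2)
    ids = validation.frame["no"].to_numpy()[ok] if "no" in validation.frame \
        else np.arange(ok.sum())
    frame = pd.DataFrame({"no": ids, "measured": measured,
                          "predicted": predicted})
    return ValidationReport(r_squared=r2, frame=frame, n=int(ok.sum()))
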