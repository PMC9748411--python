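"""Impedance indices, condition factors, and the nonadipose-mass calibration.

The calibration regresses CT-derived nonadipose mass (kg) on an impedance
index (length^2/resistance, cm^2/ohm), total body mass (kg) and time after
capture (h), by ordinary least squares with an intercept. Adipose mass is
then predicted by difference with body mass. Candidate indices (SCL or CCL
as length; Rinf, R0, R50, Ri or Xc50 as resistance) are compared by the
small-sample corrected Akaike information criterion; an exhaustive search
over the candidate set replaces path-dependent stepwise selection, which
reaches the identical optimum for this model family.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .errors import ArgumentError, FitError
from .synthetic import Cohort, ImpedanceMeasurement

__all__ = [
    "LENGTH_BASES",
    "RESISTANCE_BASES",
    "IndexSpec",
    "CalibrationModel",
    "SplitResult",
    "AdiposePrediction",
    "fulton_k",
    "impedance_index",
    "average_replicates",
    "cohort_design_frame",
    "fit_calibration",
    "select_model",
    "split_validate",
    "predict_adipose_mass",
    "load_equation",
    "list_equations",
    "aicc_from_ols",
]

LENGTH_BASES = ("scl", "ccl")
RESISTANCE_BASES = ("rinf", "r0", "r50", "ri", "xc50")

_LENGTH_COL = {"scl": "scl_cm", "ccl": "ccl_cm"}
_RES_COL = {"rinf": "rinf_ohm", "r0": "r0_ohm", "r50": "r50_ohm",
            "ri": "ri_ohm", "xc50": "xc50_ohm"}


@dataclass(frozen=True, order=True)
class IndexSpec:
    """An impedance-index choice: which length and which resistance."""

    length_basis: str
    resistance_basis: str

    def __post_init__(self) -> None:
        if self.length_basis not in LENGTH_BASES:
            raise ArgumentError(f"length_basis must be one of {LENGTH_BASES}")
        if self.resistance_basis not in RESISTANCE_BASES:
            raise ArgumentError(f"resistance_basis must be one of {RESISTANCE_BASES}")

    @property
    def column(self) -> str:
        return f"{self.length_basis}2_{self.resistance_basis}"

    def __str__(self) -> str:
        return f"{self.length_basis.upper()}^2/{self.resistance_basis.upper()}"


ALL_INDEX_SPECS = tuple(IndexSpec(l, r) for l in LENGTH_BASES for r in RESISTANCE_BASES)


@dataclass
class CalibrationModel:
    """Fitted (or fixture) coefficients for nonadipose-mass prediction.

    ``beta0`` kg, ``beta_index`` kg per (cm^2/ohm), ``beta_mass``
    dimensionless, ``beta_time`` kg/h (``None`` when the time term is
    excluded). Fit statistics are ``None`` on fixture models loaded from the
    shipped coefficient table.
    """

    beta0: float
    beta_index: float
    beta_mass: float
    beta_time: float | None
    index_spec: IndexSpec
    n_fit: int
    r2: float | None = None
    rmse: float | None = None
    f_stat: float | None = None
    f_df: tuple[int, int] | None = None
    aicc: float | None = None
    name: str | None = None

    def __post_init__(self) -> None:
        if self.r2 is not None and not (-1e-12 <= self.r2 <= 1 + 1e-12):
            raise ArgumentError("r2 must lie in [0, 1]")
        if self.rmse is not None and self.rmse < 0:
            raise ArgumentError("rmse must be >= 0")
        k = 3 + (self.beta_time is not None)
        if self.r2 is not None and self.n_fit <= k:
            raise ArgumentError("n_fit must exceed the number of coefficients")

    @property
    def n_params(self) -> int:
        """Coefficients incl. intercept, excl. the variance parameter."""
        return 3 + (self.beta_time is not None)

    def predict_nonat(self, body_mass, index, time) -> np.ndarray:
        bt = 0.0 if self.beta_time is None else self.beta_time
        return (self.beta0 + self.beta_index * np.asarray(index, float)
                + self.beta_mass * np.asarray(body_mass, float)
                + bt * np.asarray(time, float))

    def to_dict(self) -> dict:
        d = {
            "name": self.name,
            "index": self.index_spec.column,
            "beta0": self.beta0,
            "beta_index": self.beta_index,
            "beta_mass": self.beta_mass,
            "beta_time": self.beta_time,
            "n_fit": self.n_fit,
            "r2": self.r2,
            "rmse": self.rmse,
            "f_stat": self.f_stat,
            "f_df": list(self.f_df) if self.f_df else None,
            "aicc": self.aicc,
        }
        return d


class AdiposePrediction(NamedTuple):
    """Predicted adipose mass (kg) and whether it was clipped to [0, mass]."""

    value: np.ndarray | float
    clipped: np.ndarray | bool


@dataclass
class SplitResult:
    """A 2/3-1/3 split-validation outcome."""

    fit_ids: list[str]
    test_ids: list[str]
    model: CalibrationModel
    test_predictions: pd.Series  # adipose mass (kg) per test animal


# ---------------------------------------------------------------------------
# Elementary quantities
# ---------------------------------------------------------------------------


def fulton_k(body_mass, scl):
    """Fulton's condition factor K = body mass / SCL^3 * 10,000 (kg, cm)."""
    body_mass = np.asarray(body_mass, float)
    scl = np.asarray(scl, float)
    if np.any(scl <= 0):
        raise ArgumentError("scl must be positive")
    if np.any(body_mass < 0):
        raise ArgumentError("body_mass must be nonnegative")
    out = body_mass / scl ** 3 * 1e4
    return float(out) if out.ndim == 0 else out


def impedance_index(length, resistance):
    """Impedance index length^2/resistance (cm^2/ohm)."""
    length = np.asarray(length, float)
    resistance = np.asarray(resistance, float)
    if np.any(length <= 0):
        raise ArgumentError("length must be positive")
    if np.any(resistance <= 0):
        raise ArgumentError("resistance must be positive (bad sweep extraction?)")
    out = length ** 2 / resistance
    return float(out) if out.ndim == 0 else out


def average_replicates(measurements: Sequence[ImpedanceMeasurement]) -> ImpedanceMeasurement:
    """Arithmetic mean of replicate sweeps (the pre-index aggregation)."""
    if not measurements:
        raise ArgumentError("no replicates to average")
    mean = lambda attr: float(np.mean([getattr(m, attr) for m in measurements]))
    return ImpedanceMeasurement(
        r0=mean("r0"), rinf=mean("rinf"), r50=mean("r50"), ri=mean("ri"),
        xc50=mean("xc50"), pha50=mean("pha50"), n_replicates=len(measurements),
    )


def cohort_design_frame(cohort: Cohort | pd.DataFrame,
                        nonat_mass: Sequence[float] | pd.Series | None = None) -> pd.DataFrame:
    """Build the regression frame: ids, predictors, all ten index columns.

    ``nonat_mass`` is the CT-derived response (kg). When omitted, the
    synthetic CT measurement (``nonat_ct_kg``) is used if present, falling
    back to the noise-free truth ``(1 - f) * mass``.
    """
    df = cohort.to_frame() if isinstance(cohort, Cohort) else cohort.copy()
    out = df[["id", "body_mass_kg", "time_after_capture_h"]].copy()
    for spec in ALL_INDEX_SPECS:
        out[spec.column] = impedance_index(df[_LENGTH_COL[spec.length_basis]],
                                           df[_RES_COL[spec.resistance_basis]])
    if nonat_mass is not None:
        out["nonat_mass_kg"] = np.asarray(nonat_mass, float)
    elif "nonat_mass_kg" in df:
        out["nonat_mass_kg"] = df["nonat_mass_kg"]
    elif "nonat_ct_kg" in df and df["nonat_ct_kg"].notna().all():
        out["nonat_mass_kg"] = df["nonat_ct_kg"].astype(float)
    elif "true_at_fraction" in df and df["true_at_fraction"].notna().all():
        out["nonat_mass_kg"] = (1.0 - df["true_at_fraction"]) * df["body_mass_kg"]
    return out


# ---------------------------------------------------------------------------
# Fitting and selection
# ---------------------------------------------------------------------------


def aicc_from_ols(ssr: float, n: int, k: int) -> float:
    """Small-sample corrected AIC with Gaussian log-likelihood.

    ``k`` counts intercept + slopes + the variance parameter. The maximum
    likelihood variance is SSR/n, giving AIC = n*log(2*pi*SSR/n) + n + 2k and
    AICc = AIC + 2k(k+1)/(n-k-1).
    """
    if n - k - 1 <= 0:
        raise ArgumentError("n too small for AICc")
    loglik = -0.5 * n * (math.log(2 * math.pi * ssr / n) + 1.0)
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_calibration(design: pd.DataFrame, index_spec: IndexSpec | str,
                    include_time: bool = True) -> CalibrationModel:
    """OLS fit of nonadipose mass on {index, body mass, time}.

    ``index_spec`` may also name an arbitrary column of ``design`` to use as
    the index predictor (e.g. for sensitivity checks against a noise
    predictor). Raises :class:`FitError` on a rank-deficient design, naming
    the collinear columns.
    """
    col = index_spec.column if isinstance(index_spec, IndexSpec) else index_spec
    spec = index_spec if isinstance(index_spec, IndexSpec) else IndexSpec("scl", "r50")
    predictors = [col, "body_mass_kg"] + (["time_after_capture_h"] if include_time else [])
    needed = predictors + ["nonat_mass_kg"]
    missing = [c for c in needed if c not in design]
    if missing:
        raise ArgumentError(f"design frame lacks columns: {missing}")
    sub = design[needed]
    if sub.isna().any().any():
        raise ArgumentError("missing values in predictors or response")
    n = len(sub)
    p = len(predictors) + 1
    if n < p + 2:
        raise ArgumentError(f"need at least {p + 2} rows to fit, got {n}")
    X = sm.add_constant(sub[predictors].to_numpy(float), has_constant="add")
    if np.linalg.matrix_rank(X) < X.shape[1]:
        corr = np.corrcoef(X[:, 1:], rowvar=False)
        pairs = [
            f"{predictors[i]}~{predictors[j]}"
            for i in range(len(predictors)) for j in range(i + 1, len(predictors))
            if abs(corr[i, j]) > 1 - 1e-10
        ]
        raise FitError("rank-deficient design; collinear columns: "
                       + (", ".join(pairs) or "constant predictor"))
    res = sm.OLS(sub["nonat_mass_kg"].to_numpy(float), X).fit()
    beta = res.params
    df_resid = int(res.df_resid)
    return CalibrationModel(
        beta0=float(beta[0]),
        beta_index=float(beta[1]),
        beta_mass=float(beta[2]),
        beta_time=float(beta[3]) if include_time else None,
        index_spec=spec,
        n_fit=n,
        r2=float(min(max(res.rsquared, 0.0), 1.0)),
        rmse=float(np.sqrt(res.ssr / df_resid)),
        f_stat=float(res.fvalue),
        f_df=(int(res.df_model), df_resid),
        aicc=aicc_from_ols(float(res.ssr), n, p + 1),
        name=col,
    )


def select_model(design: pd.DataFrame,
                 candidates: Iterable[IndexSpec | str] = ALL_INDEX_SPECS,
                 include_time: bool = True) -> list[CalibrationModel]:
    """Fit every candidate index and rank ascending by AICc.

    Ties are broken by fewer parameters, then lexicographic index name. The
    ranking does not depend on the input order of the candidates. Raises
    :class:`FitError` if every candidate fit fails.
    """
    candidates = list(candidates)
    if not candidates:
        raise ArgumentError("need at least one candidate index")
    fits, failures = [], []
    for cand in candidates:
        try:
            fits.append(fit_calibration(design, cand, include_time=include_time))
        except (ArgumentError, FitError) as exc:
            failures.append(f"{cand}: {exc}")
    if not fits:
        raise FitError("all candidate fits failed: " + "; ".join(failures))
    fits.sort(key=lambda m: (m.aicc, m.n_params, m.name))
    return fits


def split_validate(design: pd.DataFrame, index_spec: IndexSpec | str,
                   seed: int | None = None) -> SplitResult:
    """Seeded random 2/3-1/3 split; fit on the 2/3, predict on the 1/3.

    The fit set holds ceil(2n/3) animals (33 of 49), the test set the rest.
    """
    n = len(design)
    if n < 9:
        raise ArgumentError("need at least 9 animals to split-validate")
    n_fit = math.ceil(2 * n / 3)
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    fit_rows = design.iloc[np.sort(order[:n_fit])]
    test_rows = design.iloc[np.sort(order[n_fit:])]
    model = fit_calibration(fit_rows, index_spec)
    col = index_spec.column if isinstance(index_spec, IndexSpec) else index_spec
    pred = predict_adipose_mass(
        test_rows["body_mass_kg"].to_numpy(float),
        test_rows[col].to_numpy(float),
        test_rows["time_after_capture_h"].to_numpy(float),
        model,
    )
    return SplitResult(
        fit_ids=fit_rows["id"].astype(str).tolist(),
        test_ids=test_rows["id"].astype(str).tolist(),
        model=model,
        test_predictions=pd.Series(pred.value, index=test_rows["id"].astype(str),
                                   name="at_mass_kg"),
    )


def predict_adipose_mass(body_mass, index, time, model: CalibrationModel) -> AdiposePrediction:
    """Adipose mass = body mass - predicted nonadipose mass, clipped to
    [0, body mass] with a clip flag."""
    body_mass = np.asarray(body_mass, float)
    if np.any(body_mass <= 0):
        raise ArgumentError("body_mass must be positive")
    if np.any(np.asarray(time, float) < 0):
        raise ArgumentError("time must be >= 0")
    raw = body_mass - model.predict_nonat(body_mass, index, time)
    value = np.clip(raw, 0.0, body_mass)
    clipped = value != raw
    if value.ndim == 0:
        return AdiposePrediction(float(value), bool(clipped))
    return AdiposePrediction(value, clipped)


# ---------------------------------------------------------------------------
# Shipped printed-equation fixtures
# ---------------------------------------------------------------------------


def _equation_table() -> dict:
    with resources.files("turtlebis.data").joinpath("equations.json").open() as fh:
        return json.load(fh)


def list_equations() -> list[str]:
    return sorted(_equation_table())


def load_equation(name: str) -> CalibrationModel:
    """Load one of the published coefficient sets by name.

    Available: ``prediction_scl_r50``/``prediction_ccl_r50`` (fit on the 2/3
    prediction group) and ``final_scl_r50``/``final_ccl_r50`` (full-sample
    equations recommended for field use).
    """
    table = _equation_table()
    if name not in table:
        raise ArgumentError(f"unknown equation {name!r}; choose from {sorted(table)}")
    e = table[name]
    return CalibrationModel(
        beta0=e["intercept"], beta_index=e["index"], beta_mass=e["body_mass"],
        beta_time=e["time"],
        index_spec=IndexSpec(e["length_basis"], e["resistance_basis"]),
        n_fit=e["n_fit"], name=name,
    )
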