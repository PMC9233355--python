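"""Calibration of the raw pool genetic map length (PGM -> nPGM).

The raw PGM systematically underestimates genetic length, and the bias
depends on genotyping depth (number of assayed markers, "n_snps") and
population size ("n_genotypes"). The correction factor for one sample is

    adj_start = ML_ref / ML_PGM

the ratio of the reference map length to the raw PGM length, both summed
over all chromosomes. Two regression models predict adj_start from the two
design variables:

  linear (no intercept):  adj_start = a * n_snps + b * n_genotypes
  non-linear:             adj_start = alpha * exp(beta  * log2 n_snps)
                                            * exp(gamma * log2 n_genotypes)
                                      + theta / sqrt(n_snps)

Model choice is by AIC / log-likelihood under i.i.d. Gaussian residuals; the
non-linear model wins and its prediction rescales every K factor:
K' = K * adj_start, whose cumulation is the adjusted map, nPGM.

A pre-fitted non-linear model for F2 populations genotyped by SNP-array
pooling ships with the package (default_model); its coefficients were
estimated on a 1260-population simulation grid against a barley consensus
map. It does not transfer to other population types: RIL maps are expanded
roughly two-fold relative to F2.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

CALIBRATION_COLUMNS = ["n_snps", "n_genotypes", "ml_ref", "ml_pgm", "adj_start"]

#: Haldane-Waddington map expansion of fully selfed RIL relative to F2.
RIL_EXPANSION = 2.0


class FitError(RuntimeError):
    """Raised when a calibration model cannot be fitted."""


class PopulationTypeError(ValueError):
    """Raised when a model is applied to an incompatible population type."""


def adj_start_observed(ml_ref: float, ml_pgm: float) -> float:
    """Observed correction factor: reference map length over raw PGM length."""
    if ml_ref <= 0:
        raise ValueError("reference map length must be positive")
    if ml_pgm <= 0:
        raise ValueError("degenerate PGM: raw map length must be positive")
    return float(ml_ref) / float(ml_pgm)


def _gaussian_loglik(residuals: np.ndarray) -> float:
    """Gaussian log-likelihood at the MLE variance sigma^2 = RSS / n."""
    n = residuals.size
    rss = float(np.dot(residuals, residuals))
    if rss <= 0:
        rss = np.finfo(float).tiny * n
    sigma2 = rss / n
    return -0.5 * n * (math.log(2 * math.pi * sigma2) + 1.0)


@dataclass
class LinearAdjModel:
    """Linear no-intercept correction model: adj_start = a*n_snps + b*n_genotypes."""

    a: float
    b: float
    loglik: float = float("nan")
    aic: float = float("nan")
    n: int = 0

    def predict(self, n_snps, n_genotypes):
        return self.a * np.asarray(n_snps, float) + self.b * np.asarray(
            n_genotypes, float
        )


@dataclass
class AdjustmentModel:
    """Non-linear correction model with coefficients alpha, beta, gamma, theta."""

    alpha: float
    beta: float
    gamma: float
    theta: float
    population_type: str = "F2"
    loglik: float = float("nan")
    aic: float = float("nan")
    n: int = 0
    converged: bool = True
    provenance: str = field(default="refit")

    def predict(self, n_snps, n_genotypes):
        s = np.asarray(n_snps, float)
        g = np.asarray(n_genotypes, float)
        if np.any(s < 2) or np.any(g < 1):
            raise ValueError("need n_snps >= 2 and n_genotypes >= 1")
        return (
            self.alpha
            * np.exp(self.beta * np.log2(s))
            * np.exp(self.gamma * np.log2(g))
            + self.theta / np.sqrt(s)
        )

    def to_dict(self) -> dict:
        return {
            "alpha": self.alpha,
            "beta": self.beta,
            "gamma": self.gamma,
            "theta": self.theta,
            "population_type": self.population_type,
            "provenance": self.provenance,
            "fit": {"loglik": self.loglik, "aic": self.aic, "n": self.n},
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)
            fh.write("\n")

    @classmethod
    def from_dict(cls, d: dict) -> "AdjustmentModel":
        fit = d.get("fit", {})
        return cls(
            alpha=float(d["alpha"]),
            beta=float(d["beta"]),
            gamma=float(d["gamma"]),
            theta=float(d["theta"]),
            population_type=d.get("population_type", "F2"),
            provenance=d.get("provenance", "file"),
            loglik=float(fit.get("loglik", float("nan"))),
            aic=float(fit.get("aic", float("nan"))),
            n=int(fit.get("n", 0)),
        )

    @classmethod
    def from_json(cls, path) -> "AdjustmentModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def default_model() -> AdjustmentModel:
    """The shipped F2 / SNP-array-pool correction model.

    Coefficients were fitted on a 1260-population F2 simulation grid (seven
    population sizes x nine genotyping depths x 20 replicates) against a
    42,077-marker barley consensus map. Valid for F2 pools only.
    """
    return AdjustmentModel(
        alpha=7958.92,
        beta=-0.5401,
        gamma=0.3491,
        theta=691.0495,
        population_type="F2",
        provenance="shipped: F2, SNP-array-pool",
    )


def _check_table(table: pd.DataFrame) -> pd.DataFrame:
    for col in ("n_snps", "n_genotypes", "adj_start"):
        if col not in table.columns:
            raise ValueError(f"calibration table lacks column {col!r}")
    if len(table) < 3:
        raise FitError("need at least 3 calibration rows")
    if table["n_snps"].nunique() < 2 or table["n_genotypes"].nunique() < 2:
        raise FitError("need at least 2 distinct depths and 2 distinct sizes")
    if (table["adj_start"] <= 0).any():
        raise ValueError("adj_start must be positive")
    return table


def fit_linear(table: pd.DataFrame) -> LinearAdjModel:
    """Least-squares fit of the no-intercept linear model, with logLik/AIC.

    AIC = 2k - 2 logLik with k = 3 (two coefficients plus the residual
    variance).
    """
    table = _check_table(table)
    X = table[["n_snps", "n_genotypes"]].to_numpy(float)
    y = table["adj_start"].to_numpy(float)
    if np.linalg.matrix_rank(X) < 2:
        raise FitError("design is rank deficient (constant predictor column)")
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ll = _gaussian_loglik(resid)
    return LinearAdjModel(
        a=float(coef[0]), b=float(coef[1]), loglik=ll, aic=2 * 3 - 2 * ll, n=len(y)
    )


def fit_nls(
    table: pd.DataFrame,
    init: tuple[float, float, float, float] | None = None,
    max_iter: int = 10_000,
    tol: float = 1e-10,
    population_type: str = "F2",
) -> AdjustmentModel:
    """Non-linear least-squares fit of the depth/size correction model.

    Minimizes the residual sum of squares of
    adj_start - [alpha * n_snps^(beta/ln2 scale) * n_genotypes^(gamma scale)
    + theta/sqrt(n_snps)] via trust-region least squares. Default starting
    values are alpha = median(adj_start), beta = -0.5, gamma = 0.35,
    theta = 0 — near the regime the model was designed for, since the
    surface can be multi-modal. AIC uses k = 5 (four coefficients plus the
    residual variance). Non-convergence raises with best-so-far diagnostics.
    """
    table = _check_table(table)
    s = table["n_snps"].to_numpy(float)
    g = table["n_genotypes"].to_numpy(float)
    y = table["adj_start"].to_numpy(float)
    ls2, lg2 = np.log2(s), np.log2(g)

    def model(p):
        a, b, c, t = p
        return a * np.exp(b * ls2) * np.exp(c * lg2) + t / np.sqrt(s)

    def resid(p):
        return y - model(p)

    if init is None:
        init = (float(np.median(y)), -0.5, 0.35, 0.0)
    sol = least_squares(
        resid, x0=np.asarray(init, float), xtol=tol, ftol=tol, gtol=tol,
        max_nfev=max_iter, method="lm" if len(y) >= 4 else "trf",
    )
    if not sol.success or not np.all(np.isfinite(sol.x)):
        raise FitError(
            f"non-linear fit did not converge: {sol.message}; "
            f"best-so-far params {sol.x.tolist()}, cost {sol.cost:.6g}"
        )
    ll = _gaussian_loglik(resid(sol.x))
    mod = AdjustmentModel(
        alpha=float(sol.x[0]),
        beta=float(sol.x[1]),
        gamma=float(sol.x[2]),
        theta=float(sol.x[3]),
        population_type=population_type,
        loglik=ll,
        aic=2 * 5 - 2 * ll,
        n=len(y),
        converged=True,
    )
    # refuse fits that predict nonsense on their own grid
    if np.any(mod.predict(s, g) <= 0):
        raise FitError("fitted model predicts non-positive adjustment on its grid")
    return mod


def predict_adj(model: AdjustmentModel, n_snps: int, n_genotypes: int) -> float:
    """Correction factor for one sample's depth and size; must be positive."""
    if n_snps < 2:
        raise ValueError("n_snps must be >= 2")
    if n_genotypes < 1:
        raise ValueError("n_genotypes must be >= 1")
    val = float(model.predict(n_snps, n_genotypes))
    if not math.isfinite(val) or val <= 0:
        raise ValueError(
            f"non-positive adjustment {val:.4g} at "
            f"(n_snps={n_snps}, n_genotypes={n_genotypes}): outside calibrated domain"
        )
    return val


def apply_adjustment(pairs: pd.DataFrame, adj_start: float) -> pd.DataFrame:
    """Scale every K by adj_start into the calibrated column 'k_adj'.

    The nPGM built from k_adj has exactly adj_start times the raw PGM's
    length; windowed recombination-rate correlations are unchanged by this
    pure rescaling.
    """
    if adj_start <= 0:
        raise ValueError("adj_start must be positive")
    out = pairs.copy()
    out["k_adj"] = out["k"].to_numpy(float) * float(adj_start)
    return out


def check_population_type(
    model: AdjustmentModel, pop_type: str, allow_ril_heuristic: bool = False
) -> float:
    """Guard model/population compatibility; returns an extra scale factor.

    The shipped model is calibrated for F2 pools. Using it on RIL data is
    refused unless allow_ril_heuristic is set, in which case the prediction
    is scaled by the Haldane-Waddington two-fold map expansion of fully
    selfed lines — a crude heuristic; the principled route is refitting the
    model on a RIL calibration grid.
    """
    if pop_type == model.population_type:
        return 1.0
    if pop_type == "RIL" and model.population_type == "F2":
        if not allow_ril_heuristic:
            raise PopulationTypeError(
                "model is calibrated for F2 pools but the sample is RIL; "
                "refit with a RIL grid or opt in to the factor-2 heuristic"
            )
        return RIL_EXPANSION
    raise PopulationTypeError(
        f"model population type {model.population_type!r} incompatible with "
        f"sample type {pop_type!r}"
    )
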