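"""Exact Gaussian-process regression from (sex, age, measurement) to z-score.

The model treats the tabulated reference points as noisy observations of a
latent z-score surface over the three predictors sex, age in months and the
measurement itself.  With a zero prior mean (z-scores are centred by
construction) and a stationary kernel k, the posterior at a test point x* is

    mean  = k_*^T (K + s_n^2 I)^{-1} t
    var   = k(x*, x*) - k_*^T (K + s_n^2 I)^{-1} k_* + s_n^2

Hyperparameters maximize the log marginal likelihood

    log p(t) = -1/2 t^T a - sum_i log L_ii - n/2 log 2 pi,   a = (K + s_n^2 I)^{-1} t

by multi-start quasi-Newton ascent in log-parameter space with analytic
gradients.  Predictors are standardized to zero mean and unit variance using
training statistics stored in the model, so one shared length scale is
meaningful across age (0-240 months) and measurement scales.

Organized in the Model/Results style: :class:`GPZScore` holds the data and
`fit()` returns a :class:`GPZScoreResults` carrying estimates, diagnostics,
prediction and persistence.  ``gp_fit`` / ``gp_predict`` are thin functional
wrappers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, cholesky, solve_triangular
from scipy.optimize import minimize

from .kernels import FAMILIES, KernelSpec, kernel_gradients, kernel_matrix
from .types import (
    AGE_MAX_MONTHS,
    AGE_MIN_MONTHS,
    MeasurementKind,
    Observation,
    OutOfRangeError,
    PedzError,
    Sex,
    ValidationError,
)

SCHEMA_VERSION = 1
SEX_ENCODING = {"male": 0.0, "female": 1.0}

_JITTERS = (0.0, 1e-8, 1e-7, 1e-6, 1e-5, 1e-4)

_LOG_BOUNDS = {
    "signal_variance": (-20.0, 20.0),
    "length_scale": (-10.0, 10.0),
    "alpha": (-5.0, 5.0),
    "noise_variance": (math.log(1e-10), 5.0),
}


class NumericalError(PedzError, RuntimeError):
    """Covariance matrix not positive definite even after jitter escalation."""


@dataclass(frozen=True)
class FitMetrics:
    """Regression fit metrics in z-score units; r2 stored as a fraction."""

    r2: float
    rmse: float
    mse: float
    mae: float
    degenerate: bool = False  # zero-variance truth: r2 undefined

    @property
    def r2_pct(self) -> float:
        return 100.0 * self.r2

    def as_dict(self) -> dict:
        return {
            "r2_pct": self.r2_pct,
            "rmse": self.rmse,
            "mse": self.mse,
            "mae": self.mae,
        }


def compute_metrics(truth, predicted) -> FitMetrics:
    """R^2, RMSE, MSE and MAE between true and predicted z-scores."""
    t = np.asarray(truth, dtype=float)
    p = np.asarray(predicted, dtype=float)
    if t.size == 0 or t.shape != p.shape:
        raise ValidationError("truth and predicted must be equal-length, non-empty")
    err = p - t
    mse = float(np.mean(err**2))
    mae = float(np.mean(np.abs(err)))
    ss_tot = float(np.sum((t - t.mean()) ** 2))
    if ss_tot == 0.0:
        return FitMetrics(r2=float("nan"), rmse=math.sqrt(mse), mse=mse, mae=mae,
                          degenerate=True)
    r2 = 1.0 - float(np.sum(err**2)) / ss_tot
    return FitMetrics(r2=r2, rmse=math.sqrt(mse), mse=mse, mae=mae)


def _chol_with_jitter(K: np.ndarray) -> tuple[np.ndarray, float]:
    for jit in _JITTERS:
        try:
            L = cholesky(K + jit * np.eye(K.shape[0]), lower=True)
            return L, jit
        except np.linalg.LinAlgError:
            continue
    raise NumericalError(
        "covariance matrix not positive definite after jitter up to 1e-4"
    )


def _param_names(family: str, ard: bool, ndim: int) -> list[str]:
    names = ["signal_variance"]
    if ard:
        names += [f"length_scale_{d}" for d in range(ndim)]
    else:
        names += ["length_scale"]
    if family == "rational_quadratic":
        names += ["alpha"]
    names += ["noise_variance"]
    return names


def _bound_for(name: str) -> tuple[float, float]:
    key = "length_scale" if name.startswith("length_scale") else name
    return _LOG_BOUNDS[key]


class GPZScore:
    """Gaussian-process z-score model for one measurement kind.

    Parameters
    ----------
    X : (n, 3) array
        Raw predictors ``[sex_code, age_months, measurement]`` with sex coded
        male=0, female=1.
    t : (n,) array
        Target z-scores.
    kind : MeasurementKind
        Which reference the measurements belong to.
    kernel : str
        Kernel family; the squared exponential is the shipped default.
    ard : bool
        One length scale per predictor instead of a shared isotropic scale.
    """

    def __init__(self, X, t, kind: MeasurementKind, kernel: str = "squared_exponential",
                 ard: bool = False):
        X = np.atleast_2d(np.asarray(X, dtype=float))
        t = np.asarray(t, dtype=float)
        if X.shape[0] != t.size:
            raise ValidationError("X and t lengths differ")
        if X.shape[0] < 10:
            raise ValidationError("need at least 10 training points")
        if kernel not in FAMILIES:
            raise ValidationError(f"unknown kernel family {kernel!r}")
        self.X_raw = X
        self.t = t
        self.kind = MeasurementKind.from_any(kind)
        self.kernel_family = kernel
        self.ard = ard
        self.shift = X.mean(axis=0)
        scale = X.std(axis=0)
        self.scale = np.where(scale > 0, scale, 1.0)
        self.Xs = (X - self.shift) / self.scale

    @classmethod
    def from_grid(cls, grid, kernel: str = "squared_exponential", ard: bool = False):
        """Build the model from a reference z-score grid (the training currency)."""
        flat = grid.flatten()
        X = np.column_stack(
            [
                [SEX_ENCODING[s] for s in flat["sex"]],
                flat["age_months"].to_numpy(dtype=float),
                flat["value"].to_numpy(dtype=float),
            ]
        )
        return cls(X, flat["z"].to_numpy(dtype=float), grid.kind, kernel, ard)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, kind, z_col: str = "z",
                       kernel: str = "squared_exponential", ard: bool = False):
        """Build from a long-form frame with columns sex, age_months, value, z."""
        X = np.column_stack(
            [
                [SEX_ENCODING[Sex.from_any(s).value] for s in df["sex"]],
                df["age_months"].to_numpy(dtype=float),
                df["value"].to_numpy(dtype=float),
            ]
        )
        return cls(X, df[z_col].to_numpy(dtype=float), kind, kernel, ard)

    # -- marginal likelihood -------------------------------------------------

    def _unpack(self, theta: np.ndarray) -> tuple[KernelSpec, float]:
        names = self.param_names
        vals = dict(zip(names, np.exp(theta)))
        if self.ard:
            ls = tuple(vals[f"length_scale_{d}"] for d in range(self.Xs.shape[1]))
        else:
            ls = vals["length_scale"]
        spec = KernelSpec(
            family=self.kernel_family,
            signal_variance=vals["signal_variance"],
            length_scale=ls,
            alpha=vals.get("alpha"),
        )
        return spec, vals["noise_variance"]

    @property
    def param_names(self) -> list[str]:
        return _param_names(self.kernel_family, self.ard, self.Xs.shape[1])

    def loglike(self, theta: np.ndarray) -> float:
        """Log marginal likelihood at log-parameters ``theta``."""
        return -self._nll_and_grad(theta)[0]

    def _nll_and_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        spec, noise = self._unpack(theta)
        n = self.Xs.shape[0]
        K = kernel_matrix(spec, self.Xs, self.Xs) + noise * np.eye(n)
        L, _ = _chol_with_jitter(K)
        a = cho_solve((L, True), self.t)
        nll = (
            0.5 * float(self.t @ a)
            + float(np.sum(np.log(np.diag(L))))
            + 0.5 * n * math.log(2.0 * math.pi)
        )
        Kinv = cho_solve((L, True), np.eye(n))
        grads = kernel_gradients(spec, self.Xs)
        grads["noise_variance"] = noise * np.eye(n)
        g = np.empty(len(self.param_names))
        for i, name in enumerate(self.param_names):
            dK = grads[name]
            g[i] = 0.5 * (float(np.sum(Kinv * dK)) - float(a @ dK @ a))
        return nll, g

    # -- fitting -------------------------------------------------------------

    def fit(self, *, n_restarts: int = 5, seed: int = 0, maxiter: int = 200,
            init: KernelSpec | None = None,
            init_noise_variance: float | None = None) -> "GPZScoreResults":
        """Maximize the marginal likelihood and return a results object.

        ``n_restarts`` seeded perturbations of the initial log-parameters guard
        against local optima; the best optimum by likelihood wins.  The fit is
        deterministic for a fixed seed.
        """
        names = self.param_names
        tvar = max(float(self.t.var()), 1e-12)
        base = {}
        if init is not None:
            base["signal_variance"] = init.signal_variance
            ls = np.atleast_1d(np.asarray(init.length_scale, dtype=float))
            if self.ard:
                for d in range(self.Xs.shape[1]):
                    base[f"length_scale_{d}"] = ls[d % ls.size]
            else:
                base["length_scale"] = float(ls[0])
            if init.alpha is not None:
                base["alpha"] = init.alpha
        base.setdefault("signal_variance", tvar)
        for name in names:
            if name.startswith("length_scale"):
                base.setdefault(name, 1.0)
        if self.kernel_family == "rational_quadratic":
            base.setdefault("alpha", 1.0)
        base["noise_variance"] = (
            init_noise_variance if init_noise_variance is not None else 1e-4 * tvar
        )
        theta0 = np.array([math.log(base[n]) for n in names])
        bounds = [_bound_for(n) for n in names]

        rng = np.random.default_rng(np.random.SeedSequence([int(seed), 0x6B]))
        starts = [theta0]
        for _ in range(max(0, n_restarts - 1)):
            starts.append(theta0 + rng.normal(0.0, 0.7, size=theta0.size))

        best = None
        diverged = 0
        for s in starts:
            s = np.clip(s, [lo for lo, _ in bounds], [hi for _, hi in bounds])
            try:
                sol = minimize(
                    self._nll_and_grad,
                    s,
                    jac=True,
                    method="L-BFGS-B",
                    bounds=bounds,
                    options={"maxiter": maxiter, "gtol": 1e-9, "ftol": 1e-12},
                )
            except NumericalError:
                diverged += 1
                continue
            if best is None or sol.fun < best.fun:
                best = sol
        if best is None:
            raise NumericalError("all optimizer starts failed")
        spec, noise = self._unpack(best.x)
        return GPZScoreResults(
            self, spec, noise,
            log_marginal_likelihood=-float(best.fun),
            converged=bool(best.success),
            n_failed_starts=diverged,
        )


class GPZScoreResults:
    """Fitted GP z-score calculator: estimates, prediction, persistence."""

    def __init__(self, model: GPZScore, kernel: KernelSpec, noise_variance: float,
                 log_marginal_likelihood: float = float("nan"),
                 converged: bool = True, n_failed_starts: int = 0,
                 dual_coefficients: np.ndarray | None = None):
        self.model = model
        self.kernel = kernel
        self.noise_variance = float(noise_variance)
        self.log_marginal_likelihood = log_marginal_likelihood
        self.converged = converged
        self.n_failed_starts = n_failed_starts
        n = model.Xs.shape[0]
        K = kernel_matrix(kernel, model.Xs, model.Xs) + self.noise_variance * np.eye(n)
        self.chol_, self.jitter_ = _chol_with_jitter(K)
        if dual_coefficients is None:
            self.dual_coefficients = cho_solve((self.chol_, True), model.t)
        else:
            self.dual_coefficients = np.asarray(dual_coefficients, dtype=float)
            if self.dual_coefficients.size != n:
                raise ValidationError("dual coefficient length mismatch")

    @property
    def kind(self) -> MeasurementKind:
        return self.model.kind

    # -- prediction ----------------------------------------------------------

    def _encode(self, sex, age_months, value) -> np.ndarray:
        sex_arr = np.atleast_1d(sex)
        codes = np.array([SEX_ENCODING[Sex.from_any(s).value] for s in sex_arr])
        age = np.atleast_1d(np.asarray(age_months, dtype=float))
        val = np.atleast_1d(np.asarray(value, dtype=float))
        codes, age, val = np.broadcast_arrays(codes, age, val)
        if np.any((age < AGE_MIN_MONTHS) | (age > AGE_MAX_MONTHS)):
            raise OutOfRangeError("age outside [0, 240] months")
        if np.any(val <= 0):
            raise OutOfRangeError("measurement must be positive")
        X = np.column_stack([codes, age, val]).astype(float)
        return (X - self.model.shift) / self.model.scale

    def predict(self, sex=None, age_months=None, value=None, *,
                obs: Observation | None = None) -> tuple[np.ndarray, np.ndarray]:
        """Posterior mean and variance of the z-score.

        Accepts either a single :class:`Observation` via ``obs=`` or arrays of
        sex / age_months / value.  The variance includes the noise term and is
        clamped at zero against round-off.
        """
        if obs is not None:
            if obs.kind is not self.kind:
                raise ValidationError(
                    f"observation kind {obs.kind.code} != model kind {self.kind.code}"
                )
            sex, age_months, value = obs.sex, obs.age_months, obs.value
        Xs = self._encode(sex, age_months, value)
        k_star = kernel_matrix(self.kernel, Xs, self.model.Xs)
        mean = k_star @ self.dual_coefficients
        v = solve_triangular(self.chol_, k_star.T, lower=True)
        var = (
            self.kernel.signal_variance
            - np.sum(v**2, axis=0)
            + self.noise_variance
        )
        return mean, np.maximum(var, 0.0)

    def fittedvalues(self) -> np.ndarray:
        K = kernel_matrix(self.kernel, self.model.Xs, self.model.Xs)
        return K @ self.dual_coefficients

    @property
    def metrics(self) -> FitMetrics:
        """Training-set fit metrics (R^2, RMSE, MSE, MAE) in z-score units."""
        return compute_metrics(self.model.t, self.fittedvalues())

    # -- reporting -----------------------------------------------------------

    def summary(self) -> str:
        m = self.metrics
        ls = np.atleast_1d(np.asarray(self.kernel.length_scale, dtype=float))
        lines = [
            "Gaussian-process z-score calculator",
            "=" * 51,
            f"measurement kind      {self.kind.code} ({self.kind.units})",
            f"kernel                {self.kernel.family}",
            f"training points       {self.model.Xs.shape[0]}",
            f"signal variance       {self.kernel.signal_variance:.6g}",
            f"length scale          {np.array2string(ls, precision=4)}",
        ]
        if self.kernel.alpha is not None:
            lines.append(f"alpha                 {self.kernel.alpha:.6g}")
        lines += [
            f"noise variance        {self.noise_variance:.6g}",
            f"log marginal lik.     {self.log_marginal_likelihood:.4f}",
            f"converged             {self.converged}",
            "-" * 51,
            f"training R^2          {m.r2_pct:.2f} %",
            f"training RMSE         {m.rmse:.4f} z-units",
            f"training MAE          {m.mae:.4f} z-units",
        ]
        return "\n".join(lines)

    # -- persistence ---------------------------------------------------------

    def save(self, path) -> None:
        save_model(self, path)


def save_model(results: GPZScoreResults, path) -> None:
    """Persist a fitted model as versioned JSON at full precision."""
    model = results.model
    doc = {
        "schema_version": SCHEMA_VERSION,
        "kind": results.kind.code,
        "kernel": {
            "family": results.kernel.family,
            "signal_variance": results.kernel.signal_variance,
            "length_scale": np.atleast_1d(
                np.asarray(results.kernel.length_scale, dtype=float)
            ).tolist(),
            "alpha": results.kernel.alpha,
        },
        "noise_variance": results.noise_variance,
        "standardization": {
            "shift": model.shift.tolist(),
            "scale": model.scale.tolist(),
            "sex_encoding": SEX_ENCODING,
        },
        "training_inputs_raw": model.X_raw.tolist(),
        "training_targets": model.t.tolist(),
        "dual_coefficients": np.asarray(results.dual_coefficients).tolist(),
        "log_marginal_likelihood": results.log_marginal_likelihood,
        "ard": model.ard,
        "metrics": results.metrics.as_dict(),
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(doc, fh)


def load_model(path) -> GPZScoreResults:
    """Load a model saved by :func:`save_model`; predictions are bit-identical."""
    with open(path, encoding="utf-8") as fh:
        doc = json.load(fh)
    if doc.get("schema_version") != SCHEMA_VERSION:
        raise ValidationError(
            f"unsupported model schema {doc.get('schema_version')!r}"
        )
    kspec = doc["kernel"]
    ls = kspec["length_scale"]
    kernel = KernelSpec(
        family=kspec["family"],
        signal_variance=kspec["signal_variance"],
        length_scale=tuple(ls) if len(ls) > 1 else float(ls[0]),
        alpha=kspec.get("alpha"),
    )
    if doc["noise_variance"] <= 0:
        raise ValidationError("noise_variance must be positive")
    model = GPZScore(
        np.asarray(doc["training_inputs_raw"], dtype=float),
        np.asarray(doc["training_targets"], dtype=float),
        MeasurementKind.from_any(doc["kind"]),
        kernel=kernel.family,
        ard=bool(doc.get("ard", False)),
    )
    model.shift = np.asarray(doc["standardization"]["shift"], dtype=float)
    model.scale = np.asarray(doc["standardization"]["scale"], dtype=float)
    model.Xs = (model.X_raw - model.shift) / model.scale
    return GPZScoreResults(
        model, kernel, doc["noise_variance"],
        log_marginal_likelihood=doc.get("log_marginal_likelihood", float("nan")),
        dual_coefficients=np.asarray(doc["dual_coefficients"], dtype=float),
    )


# ---------------------------------------------------------------------------
# functional surface and kernel comparison


def gp_fit(grid, kernel: str = "squared_exponential", *, seed: int = 0,
           n_restarts: int = 5, maxiter: int = 200,
           ard: bool = False) -> tuple[GPZScoreResults, FitMetrics]:
    """Fit a GP to a reference grid; returns the results and training metrics."""
    model = GPZScore.from_grid(grid, kernel=kernel, ard=ard)
    res = model.fit(n_restarts=n_restarts, seed=seed, maxiter=maxiter)
    return res, res.metrics


def gp_predict(results: GPZScoreResults, obs: Observation) -> tuple[float, float]:
    """Posterior (mean, variance) of the z-score for one observation."""
    mean, var = results.predict(obs=obs)
    return float(mean[0]), float(var[0])


def compare_kernels(grid, *, seed: int = 0, n_restarts: int = 3,
                    maxiter: int = 200, families=FAMILIES) -> pd.DataFrame:
    """Fit every kernel family to the same grid and tabulate fit metrics.

    Returns a frame with one row per family (R^2 %, RMSE, MSE, MAE, log
    marginal likelihood), sorted best-RMSE first.
    """
    rows = []
    for fam in families:
        res, m = gp_fit(grid, kernel=fam, seed=seed, n_restarts=n_restarts,
                        maxiter=maxiter)
        rows.append(
            {
                "family": fam,
                "r2_pct": m.r2_pct,
                "rmse": m.rmse,
                "mse": m.mse,
                "mae": m.mae,
                "log_marginal_likelihood": res.log_marginal_likelihood,
            }
        )
    return pd.DataFrame(rows).sort_values("rmse").reset_index(drop=True)
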