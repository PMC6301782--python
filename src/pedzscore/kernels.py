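"""Covariance functions for the Gaussian-process z-score calculator.

Four stationary families over Euclidean distance r (per-dimension scaled when
an ARD length-scale vector is used):

* squared exponential   sigma^2 * exp(-r^2 / 2 l^2)
* exponential           sigma^2 * exp(-r / l)
* Matern 5/2            sigma^2 * (1 + s + s^2/3) * exp(-s),  s = sqrt(5) r / l
* rational quadratic    sigma^2 * (1 + r^2 / (2 a l^2))^(-a)

Gradients are with respect to the *logarithm* of each hyperparameter, the
parameterization in which the marginal likelihood is optimized.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .types import ValidationError

FAMILIES = (
    "squared_exponential",
    "exponential",
    "matern52",
    "rational_quadratic",
)


@dataclass(frozen=True)
class KernelSpec:
    family: str
    signal_variance: float = 1.0
    length_scale: float | tuple[float, ...] = 1.0
    alpha: float | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(
                f"unknown kernel family {self.family!r}; choose from {FAMILIES}"
            )
        if not self.signal_variance > 0:
            raise ValidationError("signal_variance must be positive")
        ls = np.atleast_1d(np.asarray(self.length_scale, dtype=float))
        if np.any(ls <= 0):
            raise ValidationError("length_scale must be positive")
        if self.family == "rational_quadratic":
            if self.alpha is None or not self.alpha > 0:
                raise ValidationError("rational_quadratic requires alpha > 0")
        elif self.alpha is not None:
            raise ValidationError("alpha is only meaningful for rational_quadratic")

    @property
    def ard(self) -> bool:
        return np.atleast_1d(np.asarray(self.length_scale)).size > 1

    def with_params(self, **kw) -> "KernelSpec":
        return replace(self, **kw)


def _scaled_sqdist(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    A = np.atleast_2d(np.asarray(A, dtype=float))
    B = np.atleast_2d(np.asarray(B, dtype=float))
    if A.shape[1] != B.shape[1]:
        raise ValidationError(
            f"predictor dimension mismatch: {A.shape[1]} vs {B.shape[1]}"
        )
    ls = np.atleast_1d(np.asarray(spec.length_scale, dtype=float))
    if ls.size not in (1, A.shape[1]):
        raise ValidationError(
            f"length_scale has {ls.size} entries for {A.shape[1]}-d inputs"
        )
    diff = A[:, None, :] - B[None, :, :]
    u = np.sum((diff / ls) ** 2, axis=-1)
    return np.maximum(u, 0.0)


def kernel_matrix(spec: KernelSpec, A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Covariance matrix K[i, j] = k(a_i, b_j)."""
    u = _scaled_sqdist(spec, A, B)
    sv = spec.signal_variance
    if spec.family == "squared_exponential":
        return sv * np.exp(-0.5 * u)
    if spec.family == "exponential":
        return sv * np.exp(-np.sqrt(u))
    if spec.family == "matern52":
        s = np.sqrt(5.0 * u)
        return sv * (1.0 + s + s**2 / 3.0) * np.exp(-s)
    b = 1.0 + u / (2.0 * spec.alpha)
    return sv * b ** (-spec.alpha)


def _dk_du(spec: KernelSpec, u: np.ndarray, K: np.ndarray) -> np.ndarray:
    """dK/du where u is the scaled squared distance; finite everywhere."""
    sv = spec.signal_variance
    if spec.family == "squared_exponential":
        return -0.5 * K
    if spec.family == "exponential":
        rho = np.sqrt(u)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(rho > 0, -K / (2.0 * rho), 0.0)
        return out
    if spec.family == "matern52":
        s = np.sqrt(5.0 * u)
        return -(5.0 / 6.0) * sv * (1.0 + s) * np.exp(-s)
    b = 1.0 + u / (2.0 * spec.alpha)
    return -0.5 * sv * b ** (-spec.alpha - 1.0)


def kernel_gradients(spec: KernelSpec, A: np.ndarray) -> dict[str, np.ndarray]:
    """Gradient matrices dK/d(log theta) on the training set A.

    Keys: ``signal_variance``, ``length_scale`` (or ``length_scale_<d>`` per
    dimension under ARD), and ``alpha`` for the rational quadratic.
    """
    A = np.atleast_2d(np.asarray(A, dtype=float))
    u = _scaled_sqdist(spec, A, A)
    K = kernel_matrix(spec, A, A)
    dKdu = _dk_du(spec, u, K)
    grads: dict[str, np.ndarray] = {"signal_variance": K.copy()}
    ls = np.atleast_1d(np.asarray(spec.length_scale, dtype=float))
    if ls.size == 1:
        grads["length_scale"] = -2.0 * u * dKdu
    else:
        diff = A[:, None, :] - A[None, :, :]
        for d in range(ls.size):
            w = (diff[:, :, d] / ls[d]) ** 2
            grads[f"length_scale_{d}"] = -2.0 * w * dKdu
    if spec.family == "rational_quadratic":
        a = spec.alpha
        b = 1.0 + u / (2.0 * a)
        grads["alpha"] = K * a * (-np.log(b) + u / (2.0 * a * b))
    return grads
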