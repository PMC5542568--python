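"""The logistic graded response model (GRM).

A unidimensional item response model for ordered categories. For item *j*
with discrimination :math:`\\lambda_j > 0` and strictly increasing thresholds
:math:`\\tau_{j1} < \\dots < \\tau_{j,K-1}`, the cumulative response
probabilities are logistic,

.. math::

    P(X_j \\ge c \\mid \\theta) = \\frac{1}{1 + e^{-(\\lambda_j \\theta - \\tau_{jc})}},

and category probabilities are adjacent differences. The latent trait
:math:`\\theta` carries a standard-normal prior (the identification
convention all shipped parameter values assume). This module holds the model
mathematics: category probabilities, pattern likelihoods, item and test
information, optimal (EAP) trait prediction, and classical sum scoring with
severity bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

__all__ = [
    "GRMParameters",
    "InformationCurve",
    "default_gad7_parameters",
    "category_probabilities",
    "cumulative_probabilities",
    "pattern_loglikelihood",
    "item_information",
    "test_information",
    "best_predictor",
    "eap_scores",
    "sum_score",
    "SEVERITY_CUTOFFS",
]

#: GAD-7 severity cut-offs on the raw sum score (0-21).
SEVERITY_CUTOFFS = {"mild": 5, "moderate": 10, "severe": 15}

#: Default quadrature grid for posterior (EAP) computations.
DEFAULT_GRID = np.linspace(-6.0, 6.0, 401)


@dataclass
class GRMParameters:
    """Item parameters of a logistic graded response model.

    Attributes
    ----------
    discrimination : ndarray, shape (J,)
        Slopes ``lambda_j > 0``.
    thresholds : ndarray, shape (J, K-1)
        Strictly increasing thresholds ``tau_jc`` per item, on the
        slope-intercept scale (the linear predictor is
        ``lambda_j * theta - tau_jc``).
    item_labels : list of str
    """

    discrimination: np.ndarray
    thresholds: np.ndarray
    item_labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.discrimination = np.atleast_1d(
            np.asarray(self.discrimination, dtype=float)
        )
        self.thresholds = np.atleast_2d(np.asarray(self.thresholds, dtype=float))
        if self.thresholds.shape[0] != self.discrimination.shape[0]:
            raise ValueError("one threshold row per item required")
        if not np.all(np.isfinite(self.discrimination)) or not np.all(
            np.isfinite(self.thresholds)
        ):
            raise ValueError("non-finite item parameters")
        if np.any(self.discrimination <= 0):
            raise ValueError("discriminations must be positive")
        if np.any(np.diff(self.thresholds, axis=1) <= 0):
            raise ValueError("thresholds must be strictly increasing per item")
        if not self.item_labels:
            self.item_labels = [f"item{j + 1}" for j in range(self.n_items)]

    @property
    def n_items(self) -> int:
        return self.discrimination.shape[0]

    @property
    def n_categories(self) -> int:
        return self.thresholds.shape[1] + 1

    # ------------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "GRMParameters":
        """Read an item-parameter table (columns label, lambda, tau1..)."""
        frame = pd.read_csv(path)
        tau_cols = sorted(c for c in frame.columns if c.startswith("tau"))
        return cls(
            discrimination=frame["lambda"].to_numpy(),
            thresholds=frame[tau_cols].to_numpy(),
            item_labels=[str(x) for x in frame.get("label", frame.index)],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"item": np.arange(1, self.n_items + 1)})
        out["label"] = self.item_labels
        out["lambda"] = self.discrimination
        for c in range(self.n_categories - 1):
            out[f"tau{c + 1}"] = self.thresholds[:, c]
        return out


def default_gad7_parameters() -> GRMParameters:
    """The package's shipped GAD-7 item parameters (primary-care sample)."""
    with resources.files("gad7irt.params").joinpath("gad7_grm.csv").open() as fh:
        return GRMParameters.from_csv(fh)


@dataclass
class InformationCurve:
    """Information evaluated on a latent-trait grid."""

    theta_grid: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.theta_grid = np.asarray(self.theta_grid, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.theta_grid) <= 0):
            raise ValueError("theta grid must be strictly increasing")
        if self.values.shape != self.theta_grid.shape:
            raise ValueError("grid/value shape mismatch")

    def to_frame(self, name: str = "information") -> pd.DataFrame:
        return pd.DataFrame({"theta": self.theta_grid, name: self.values})


# ----------------------------------------------------------------------
# probabilities


def cumulative_probabilities(
    params: GRMParameters, item: int, theta
) -> np.ndarray:
    """``P(X_j >= c | theta)`` for c = 1..K-1; shape ``theta.shape + (K-1,)``."""
    theta = np.asarray(theta, dtype=float)
    lam = params.discrimination[item]
    tau = params.thresholds[item]
    return expit(lam * theta[..., None] - tau)


def category_probabilities(params: GRMParameters, item: int, theta) -> np.ndarray:
    """Category probabilities ``P_jk(theta)`` for k = 0..K-1.

    ``theta`` may be scalar or an array; the category axis is appended last.
    Infinite ``theta`` yields the degenerate one-hot limits.
    """
    theta = np.asarray(theta, dtype=float)
    star = cumulative_probabilities(params, item, np.nan_to_num(theta, posinf=0, neginf=0))
    # handle +-inf as limits
    pos = np.isposinf(theta)
    neg = np.isneginf(theta)
    if pos.any() or neg.any():
        star = star.copy()
        star[pos] = 1.0
        star[neg] = 0.0
    ones = np.ones(star.shape[:-1] + (1,))
    zeros = np.zeros_like(ones)
    cum = np.concatenate([ones, star, zeros], axis=-1)
    return -np.diff(cum, axis=-1)


def pattern_loglikelihood(params: GRMParameters, pattern, theta) -> np.ndarray:
    """Log-likelihood of a response pattern at ``theta``.

    ``pattern`` is a length-J sequence of scores; ``None``/NaN entries are
    missing and contribute nothing. An all-missing pattern has log-likelihood
    0 (the flat likelihood of no data).
    """
    theta = np.asarray(theta, dtype=float)
    out = np.zeros(theta.shape)
    for j, x in enumerate(_clean_pattern(pattern, params)):
        if x is None:
            continue
        p = category_probabilities(params, j, theta)[..., x]
        out = out + np.log(np.clip(p, 1e-300, None))
    return out


def _clean_pattern(pattern, params: GRMParameters) -> list[int | None]:
    cleaned: list[int | None] = []
    if len(pattern) != params.n_items:
        raise ValueError("pattern length must equal number of items")
    for x in pattern:
        if x is None or (isinstance(x, float) and np.isnan(x)):
            cleaned.append(None)
            continue
        xi = int(x)
        if not 0 <= xi < params.n_categories:
            raise ValueError(f"score {x} outside 0..{params.n_categories - 1}")
        cleaned.append(xi)
    return cleaned


# ----------------------------------------------------------------------
# information


def item_information(
    params: GRMParameters, item: int, theta_grid=DEFAULT_GRID
) -> InformationCurve:
    """Fisher information of one item along the trait grid.

    The expected negative second derivative of the log category probability,
    :math:`\\sum_k P_{jk}(\\theta)\\,[-\\partial^2_\\theta \\ln P_{jk}(\\theta)]`,
    which for any IRT model reduces to
    :math:`\\sum_k P'_{jk}(\\theta)^2 / P_{jk}(\\theta)` because the second
    derivatives sum to zero. Derivatives of the logistic cumulative curves
    are analytic: :math:`\\partial_\\theta P^*_c = \\lambda P^*_c (1-P^*_c)`.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    lam = params.discrimination[item]
    star = cumulative_probabilities(params, item, theta_grid)
    dstar = lam * star * (1.0 - star)
    pad = np.zeros(star.shape[:-1] + (1,))
    p = -np.diff(np.concatenate([np.ones_like(pad), star, pad], axis=-1), axis=-1)
    dp = -np.diff(np.concatenate([pad, dstar, pad], axis=-1), axis=-1)
    info = np.sum(dp**2 / np.clip(p, 1e-300, None), axis=-1)
    return InformationCurve(theta_grid, info)


def test_information(
    params: GRMParameters, item_subset=None, theta_grid=DEFAULT_GRID
) -> InformationCurve:
    """Sum of item information over a subset of items (default: all)."""
    if item_subset is None:
        item_subset = range(params.n_items)
    item_subset = list(item_subset)
    if not item_subset:
        raise ValueError("item subset must be nonempty")
    theta_grid = np.asarray(theta_grid, dtype=float)
    total = np.zeros(theta_grid.shape)
    for j in item_subset:
        total += item_information(params, j, theta_grid).values
    return InformationCurve(theta_grid, total)


# ----------------------------------------------------------------------
# scoring


def best_predictor(
    params: GRMParameters, pattern, theta_grid=DEFAULT_GRID
) -> tuple[float, float]:
    """EAP (posterior-mean) trait estimate for one response pattern.

    The minimum mean-squared-error predictor of the latent trait under the
    standard-normal prior,
    :math:`\\int \\theta L(x|\\theta)\\varphi(\\theta)d\\theta /
    \\int L(x|\\theta)\\varphi(\\theta)d\\theta`, computed by trapezoid
    quadrature on a fixed grid. Returns ``(eap, posterior_sd)``. With an
    all-missing pattern the prior is returned: ``(0.0, 1.0)``.
    """
    theta_grid = np.asarray(theta_grid, dtype=float)
    cleaned = _clean_pattern(pattern, params)
    if all(x is None for x in cleaned):
        return 0.0, 1.0
    logpost = pattern_loglikelihood(params, pattern, theta_grid) + norm.logpdf(
        theta_grid
    )
    w = np.exp(logpost - logpost.max())
    z = np.trapezoid(w, theta_grid)
    mean = np.trapezoid(theta_grid * w, theta_grid) / z
    var = np.trapezoid((theta_grid - mean) ** 2 * w, theta_grid) / z
    return float(mean), float(np.sqrt(var))


def eap_scores(
    params: GRMParameters, data, theta_grid=DEFAULT_GRID
) -> pd.DataFrame:
    """EAP estimate and posterior sd for every respondent of a matrix.

    ``data`` is an :class:`~gad7irt.data.ItemResponseMatrix`. Patterns are
    scored on their observed items only; duplicated patterns are computed
    once.
    """
    vals = data.scores.astype(float)
    vals[data.missing_mask] = np.nan
    cache: dict[tuple, tuple[float, float]] = {}
    eap = np.empty(data.n_respondents)
    sd = np.empty(data.n_respondents)
    for i in range(data.n_respondents):
        key = tuple(-1 if np.isnan(v) else int(v) for v in vals[i])
        if key not in cache:
            cache[key] = best_predictor(params, vals[i], theta_grid)
        eap[i], sd[i] = cache[key]
    return pd.DataFrame({"eap": eap, "posterior_sd": sd})


def sum_score(pattern) -> tuple[int, str]:
    """Raw sum score and severity band (cut-offs 5 / 10 / 15).

    A pattern with missing entries is summed over observed items and the
    band is suffixed ``" (incomplete)"`` to flag that the score is a lower
    bound.
    """
    vals = [x for x in pattern if x is not None and not (isinstance(x, float) and np.isnan(x))]
    incomplete = len(vals) < len(pattern)
    score = int(sum(int(v) for v in vals))
    if score >= SEVERITY_CUTOFFS["severe"]:
        band = "severe"
    elif score >= SEVERITY_CUTOFFS["moderate"]:
        band = "moderate"
    elif score >= SEVERITY_CUTOFFS["mild"]:
        band = "mild"
    else:
        band = "minimal"
    if incomplete:
        band += " (incomplete)"
    return score, band
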