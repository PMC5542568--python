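"""Classical test theory statistics and maximal-reliability weighting.

Per-item means/SDs, pairwise Pearson correlations, item-restscore
correlations, Loevinger scalability coefficients (Hij / Hi), and a
Raykov-style maximal-reliability composite: a linear one-factor model is
fitted to the item covariance matrix by maximum likelihood and items are
weighted proportional to loading/uniqueness, which maximises the composite's
reliability among all weighted sum scores.

All statistics use pairwise-complete observations, so every available case
contributes to every statistic it can.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from .data import ItemResponseMatrix

__all__ = [
    "item_descriptives",
    "item_restscore",
    "scalability",
    "max_reliability_weights",
    "describe",
    "DescriptivesReport",
]


@dataclass
class DescriptivesReport:
    item_table: pd.DataFrame  # mean, sd, restscore_r, Hi per item
    correlations: pd.DataFrame  # J x J pairwise Pearson r
    scalability_pairs: pd.DataFrame  # J x J Hij
    weights: np.ndarray
    max_reliability: float
    reliability_ci: tuple[float, float] | None
    heywood: bool

    def to_text(self) -> str:
        lines = ["Item descriptives", self.item_table.to_string(float_format="%.3f")]
        lines += ["", "Pairwise correlations", self.correlations.to_string(float_format="%.3f")]
        w = ", ".join(f"{x:.2f}" for x in self.weights)
        lines += ["", f"Maximal-reliability weights (mean 1): {w}"]
        rel = f"Composite reliability: {self.max_reliability:.3f}"
        if self.reliability_ci is not None:
            rel += f" (95% bootstrap CI {self.reliability_ci[0]:.3f}-{self.reliability_ci[1]:.3f})"
        lines.append(rel)
        if self.heywood:
            lines.append("WARNING: Heywood case; uniqueness floored")
        return "\n".join(lines)


def _pairwise_stats(data: ItemResponseMatrix):
    """Pairwise-complete covariance/correlation with undefined -> NaN."""
    j = data.n_items
    vals = data.scores.astype(float)
    vals[data.missing_mask] = np.nan
    frame = pd.DataFrame(vals, columns=data.item_labels)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # zero-variance columns
        corr = frame.corr(min_periods=2)
    cov = frame.cov(min_periods=2)
    np.fill_diagonal(corr.values, 1.0)
    return corr, cov, frame


def item_descriptives(data: ItemResponseMatrix) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-item means/SDs and the pairwise Pearson correlation matrix.

    Zero-variance items get NaN correlations (flagged undefined, never
    silently zero).
    """
    corr, _, frame = _pairwise_stats(data)
    table = pd.DataFrame(
        {
            "mean": frame.mean(),
            "sd": frame.std(ddof=1),
            "n_obs": frame.notna().sum(),
        }
    )
    return table, corr


def item_restscore(data: ItemResponseMatrix) -> pd.Series:
    """Correlation of each item with the sum of the remaining items.

    Respondents missing the focal item, or any item entering its restscore,
    are dropped from that item's statistic.
    """
    if data.n_items < 3:
        raise ValueError("restscore needs at least 3 items")
    vals = data.scores.astype(float)
    vals[data.missing_mask] = np.nan
    out = {}
    for j, lab in enumerate(data.item_labels):
        rest = np.delete(vals, j, axis=1)
        ok = ~np.isnan(vals[:, j]) & ~np.isnan(rest).any(axis=1)
        x, y = vals[ok, j], rest[ok].sum(axis=1)
        out[lab] = (
            np.nan if x.std() == 0 or y.std() == 0 else float(np.corrcoef(x, y)[0, 1])
        )
    return pd.Series(out, name="restscore_r")


def _covmax(x: np.ndarray, y: np.ndarray) -> float:
    """Maximum covariance over couplings with the observed marginals.

    Attained by the comonotonic (sort-and-pair) coupling: sort both
    samples and covary them in matched order.
    """
    return float(np.cov(np.sort(x), np.sort(y), ddof=1)[0, 1])


def scalability(data: ItemResponseMatrix) -> tuple[pd.DataFrame, pd.Series]:
    """Loevinger scalability: Hij per pair and Hi per item.

    ``Hij = cov(Xi, Xj) / covmax(Xi, Xj)`` on pairwise-complete cases;
    ``Hi`` pools numerator and denominator over the item's pairs.
    Degenerate pairs (zero maximal covariance) are NaN.
    """
    j = data.n_items
    vals = data.scores.astype(float)
    vals[data.missing_mask] = np.nan
    hij = np.full((j, j), np.nan)
    cov = np.zeros((j, j))
    cmax = np.zeros((j, j))
    for a in range(j):
        for b in range(a + 1, j):
            ok = ~np.isnan(vals[:, a]) & ~np.isnan(vals[:, b])
            if ok.sum() < 2:
                continue
            x, y = vals[ok, a], vals[ok, b]
            cov[a, b] = cov[b, a] = float(np.cov(x, y, ddof=1)[0, 1])
            cm = _covmax(x, y)
            cmax[a, b] = cmax[b, a] = cm
            if cm > 0:
                hij[a, b] = hij[b, a] = cov[a, b] / cm
    hi = {}
    for a, lab in enumerate(data.item_labels):
        denom = cmax[a].sum()
        hi[lab] = cov[a].sum() / denom if denom > 0 else np.nan
    pairs = pd.DataFrame(hij, index=data.item_labels, columns=data.item_labels)
    return pairs, pd.Series(hi, name="Hi")


# ----------------------------------------------------------------------
# maximal reliability


def _fit_one_factor(cov: np.ndarray, floor: float = 1e-4):
    """ML fit of a single-factor model Sigma = loadings loadings' + diag(psi).

    Minimises the Wishart discrepancy F = log|Sigma| + tr(S Sigma^-1).
    Returns (loadings, uniquenesses, heywood_flag); a Heywood case is
    handled by flooring the uniqueness at ``floor`` times the variance.
    """
    j = cov.shape[0]
    diag = np.diag(cov)
    # principal-axis start
    w, v = np.linalg.eigh(cov)
    lam0 = v[:, -1] * np.sqrt(max(w[-1], 1e-6))
    psi0 = np.maximum(diag - lam0**2, 0.1 * diag)

    def unpack(x):
        return x[:j], np.exp(x[j:])

    def objective(x):
        lam, psi = unpack(x)
        sigma = np.outer(lam, lam) + np.diag(psi)
        try:
            chol = np.linalg.cholesky(sigma)
        except np.linalg.LinAlgError:
            return 1e10
        logdet = 2 * np.log(np.diag(chol)).sum()
        sinv = np.linalg.inv(sigma)
        return logdet + np.trace(cov @ sinv)

    x0 = np.concatenate([lam0, np.log(psi0)])
    res = optimize.minimize(objective, x0, method="L-BFGS-B")
    lam, psi = unpack(res.x)
    if lam.sum() < 0:  # sign indeterminacy
        lam = -lam
    heywood = bool(np.any(psi < floor * diag))
    psi = np.maximum(psi, floor * diag)
    return lam, psi, heywood


def max_reliability_weights(
    data: ItemResponseMatrix,
    n_bootstrap: int = 1000,
    seed: int | None = None,
) -> tuple[np.ndarray, float, tuple[float, float] | None, bool]:
    """Maximal-reliability item weights from a linear one-factor model.

    Weights are proportional to loading/uniqueness (reported rescaled to
    mean 1 — only weight ratios are interpretable) and the composite
    reliability is ``sum(lam^2/psi) / (1 + sum(lam^2/psi))``, with a
    percentile bootstrap CI over respondents (``n_bootstrap=0`` skips it).
    """
    if data.n_items < 3:
        raise ValueError("one-factor fit needs at least 3 items")
    _, cov, frame = _pairwise_stats(data)
    lam, psi, heywood = _fit_one_factor(cov.to_numpy())
    weights = lam / psi
    weights = weights / weights.mean()
    s = float(np.sum(lam**2 / psi))
    rel = s / (1.0 + s)
    ci = None
    if n_bootstrap:
        rng = np.random.default_rng(seed)
        vals = frame.to_numpy()
        n = vals.shape[0]
        boots = np.empty(n_bootstrap)
        for b in range(n_bootstrap):
            idx = rng.integers(0, n, n)
            bcov = pd.DataFrame(vals[idx]).cov(min_periods=2).to_numpy()
            if not np.all(np.isfinite(bcov)):
                boots[b] = np.nan
                continue
            bl, bp, _ = _fit_one_factor(bcov)
            sb = float(np.sum(bl**2 / bp))
            boots[b] = sb / (1.0 + sb)
        boots = boots[np.isfinite(boots)]
        ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5)))
    if heywood:
        warnings.warn("Heywood case: uniqueness floored", stacklevel=2)
    return weights, rel, ci, heywood


def describe(
    data: ItemResponseMatrix, n_bootstrap: int = 1000, seed: int | None = None
) -> DescriptivesReport:
    """Full classical item analysis of a response matrix."""
    table, corr = item_descriptives(data)
    table["restscore_r"] = item_restscore(data)
    pairs, hi = scalability(data)
    table["Hi"] = hi
    weights, rel, ci, heywood = max_reliability_weights(
        data, n_bootstrap=n_bootstrap, seed=seed
    )
    return DescriptivesReport(
        item_table=table,
        correlations=corr,
        scalability_pairs=pairs,
        weights=weights,
        max_reliability=rel,
        reliability_ci=ci,
        heywood=heywood,
    )
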