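"""Posterior predictive model criticism via pairwise item correlations.

For each retained posterior draw, a replicate dataset of the same size (and
the same missingness pattern) is simulated from the graded response model;
the pairwise item correlations of the replicates form, per item pair, a
reference distribution F against which the observed correlation t_obs is
judged by the two-sided tail probability ``2 * min(F(t_obs), 1 - F(t_obs))``.
Small values for a pair mean the model cannot reproduce that pair's
association — the signature of local dependence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bayes import PosteriorSample
from .data import ItemResponseMatrix
from .model import GRMParameters
from .synthetic import simulate_scores

__all__ = ["PPPMatrix", "posterior_predictive_pvalues"]


@dataclass
class PPPMatrix:
    """Lower-triangular posterior predictive p-values per item pair."""

    p_values: pd.DataFrame  # J x J, lower triangle filled
    t_obs: pd.DataFrame  # observed pairwise correlations
    n_replicates: int
    n_excluded: pd.DataFrame  # replicates dropped per pair (degenerate columns)

    def to_text(self) -> str:
        return (
            f"Posterior predictive p-values ({self.n_replicates} replicates)\n"
            + self.p_values.to_string(float_format="%.3f", na_rep="")
        )


def _pairwise_corr(vals: np.ndarray) -> np.ndarray:
    """Pairwise-complete correlations of a matrix with NaN missing.

    Returns a J x J array; degenerate pairs are NaN.
    """
    return pd.DataFrame(vals).corr(min_periods=2).to_numpy()


def posterior_predictive_pvalues(
    data: ItemResponseMatrix,
    sample: PosteriorSample,
    n_replicates: int | None = None,
    seed: int | None = None,
) -> PPPMatrix:
    """Posterior predictive p-values for all pairwise correlations.

    ``n_replicates`` defaults to every retained draw; fewer are taken by
    even subsampling across the retained sequence (which interleaves
    chains). Replicates reuse the observed missingness mask so the
    pairwise-complete correlations are computed on identical cells.
    Ties between t_obs and replicate values are handled mid-rank.
    """
    if sample.n_draws == 0:
        raise ValueError("posterior sample is empty")
    if n_replicates is None:
        n_replicates = sample.n_draws
    if n_replicates > sample.n_draws:
        raise ValueError("n_replicates exceeds retained draws")
    take = np.linspace(0, sample.n_draws - 1, n_replicates).round().astype(int)
    rng = np.random.default_rng(seed)
    j = data.n_items

    obs_vals = data.scores.astype(float)
    obs_vals[data.missing_mask] = np.nan
    t_obs = _pairwise_corr(obs_vals)

    rep_corr = np.empty((n_replicates, j, j))
    for r, idx in enumerate(take):
        params = GRMParameters(
            discrimination=sample.discrimination[idx],
            thresholds=sample.thresholds[idx],
            item_labels=data.item_labels,
        )
        theta = rng.standard_normal(data.n_respondents)
        rep = simulate_scores(params, theta, rng).astype(float)
        rep[data.missing_mask] = np.nan
        rep_corr[r] = _pairwise_corr(rep)

    p = np.full((j, j), np.nan)
    excl = np.zeros((j, j), dtype=int)
    for a in range(j):
        for b in range(a):
            ref = rep_corr[:, a, b]
            good = np.isfinite(ref)
            excl[a, b] = int((~good).sum())
            ref = ref[good]
            if len(ref) == 0 or not np.isfinite(t_obs[a, b]):
                continue
            # empirical CDF with mid-rank tie handling
            f = (np.sum(ref < t_obs[a, b]) + 0.5 * np.sum(ref == t_obs[a, b])) / len(ref)
            p[a, b] = 2 * min(f, 1 - f)

    labels = data.item_labels
    return PPPMatrix(
        p_values=pd.DataFrame(p, index=labels, columns=labels),
        t_obs=pd.DataFrame(t_obs, index=labels, columns=labels),
        n_replicates=n_replicates,
        n_excluded=pd.DataFrame(excl, index=labels, columns=labels),
    )
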