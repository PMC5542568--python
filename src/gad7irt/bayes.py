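"""Bayesian estimation of the logistic graded response model.

A Metropolis-within-Gibbs sampler alternating single-site random-walk
updates of (a) every respondent's latent trait, (b) each item's
discrimination on the log scale, and (c) each threshold under the order
constraint. Missing cells simply drop out of the likelihood, which under
MAR (given the trait) is equivalent to joint augmentation. Proposal scales
adapt during burn-in toward 20-50% acceptance and are frozen afterwards.

Priors: ``log lambda_j ~ N(0, 1)`` (keeps discriminations positive and
diffuse on the relevant scale), ``tau_jc ~ N(0, 10^2)`` restricted to
increasing order, ``theta_i ~ N(0, 1)`` (the identification convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .data import ItemResponseMatrix
from .model import GRMParameters

__all__ = ["GradedResponseModel", "GRMResults", "PosteriorSample", "summarize"]

_LOG_TINY = 1e-300


@dataclass
class PosteriorSample:
    """Retained MCMC draws of all item parameters.

    ``discrimination`` has shape (M, J), ``thresholds`` (M, J, K-1) and
    ``chain_id`` (M,), where M is the total number of retained draws across
    chains. ``theta`` optionally holds trait draws (M, N).
    """

    discrimination: np.ndarray
    thresholds: np.ndarray
    chain_id: np.ndarray
    theta: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if np.any(self.discrimination <= 0):
            raise ValueError("retained draws contain nonpositive discriminations")
        if np.any(np.diff(self.thresholds, axis=2) <= 0):
            raise ValueError("retained draws contain unordered thresholds")

    @property
    def n_draws(self) -> int:
        return self.discrimination.shape[0]

    @property
    def n_chains(self) -> int:
        return int(np.unique(self.chain_id).size)

    def parameter_array(self) -> tuple[np.ndarray, list[str]]:
        """Stack draws as (M, P) with parameter names lam_j / tau_j_c."""
        j = self.discrimination.shape[1]
        k1 = self.thresholds.shape[2]
        cols = [self.discrimination] + [self.thresholds[:, :, c] for c in range(k1)]
        arr = np.concatenate(cols, axis=1)
        names = [f"lambda[{i + 1}]" for i in range(j)]
        for c in range(k1):
            names += [f"tau[{i + 1},{c + 1}]" for i in range(j)]
        return arr, names

    def to_frame(self) -> pd.DataFrame:
        arr, names = self.parameter_array()
        out = pd.DataFrame(arr, columns=names)
        out.insert(0, "chain", self.chain_id)
        return out


def _column_loglik(lam, tau, theta, x, obs):
    """Per-respondent log P(x | theta) for one item; 0 where missing."""
    tau_ext = np.concatenate(([-np.inf], tau, [np.inf]))
    z = lam * theta
    with np.errstate(over="ignore"):
        p = expit(z - tau_ext[x]) - expit(z - tau_ext[x + 1])
    out = np.log(np.clip(p, _LOG_TINY, None))
    out[~obs] = 0.0
    return out


class GradedResponseModel:
    """Graded response model for an ordered categorical response matrix.

    The statsmodels-style entry point: build from data, then :meth:`fit`
    (MCMC) returns a :class:`GRMResults` with posterior summaries.

    Parameters
    ----------
    data : ItemResponseMatrix
        Responses; missing cells are allowed and handled under MAR.

    Examples
    --------
    >>> from gad7irt import GradedResponseModel, SyntheticConfig, simulate_responses
    >>> data, _, _ = simulate_responses(SyntheticConfig(n_respondents=200, seed=0))
    >>> res = GradedResponseModel(data).fit(chains=2, iterations=400,
    ...                                     burn_in=200, retained=100, seed=0)
    >>> res.summary_frame().shape[0]  # 7 slopes + 21 thresholds
    28
    """

    def __init__(self, data: ItemResponseMatrix):
        self.data = data
        self.weak_parameters: list[str] = []
        for j in range(data.n_items):
            vals, _ = data.column(j)
            seen = np.bincount(vals, minlength=data.n_categories) > 0
            if seen.sum() < 2:
                raise ValueError(
                    f"item {j + 1} shows fewer than two observed categories"
                )
            # thresholds bordering never-observed categories are weakly identified
            for c in np.flatnonzero(~seen):
                self.weak_parameters.append(f"item {j + 1} category {c}")

    @classmethod
    def from_csv(cls, path, **kwargs) -> "GradedResponseModel":
        return cls(ItemResponseMatrix.from_csv(path, **kwargs))

    @classmethod
    def from_dataframe(cls, frame, **kwargs) -> "GradedResponseModel":
        return cls(ItemResponseMatrix.from_dataframe(frame, **kwargs))

    # ------------------------------------------------------------------
    def fit(
        self,
        chains: int = 5,
        iterations: int = 6000,
        burn_in: int = 2000,
        retained: int = 1000,
        seed: int | None = None,
        store_theta: bool = False,
    ) -> "GRMResults":
        """Run the MCMC sampler and return results.

        ``retained`` is the total number of draws kept across all chains;
        thinning of the post-burn-in iterations is chosen to match it.
        """
        if burn_in >= iterations:
            raise ValueError("burn_in must be smaller than iterations")
        if chains < 1:
            raise ValueError("need at least one chain")
        post = iterations - burn_in
        per_chain = max(1, retained // chains)
        thin = max(1, post // per_chain)
        ss = np.random.SeedSequence(seed)
        states = [
            _run_chain(
                self.data, iterations, burn_in, thin, np.random.default_rng(s),
                store_theta=store_theta,
            )
            for s in ss.spawn(chains)
        ]
        for s in states:  # exact per-chain count: keep the latest draws
            for key in ("lam", "tau", "theta"):
                if key in s:
                    s[key] = s[key][-per_chain:]
        sample = PosteriorSample(
            discrimination=np.concatenate([s["lam"] for s in states]),
            thresholds=np.concatenate([s["tau"] for s in states]),
            chain_id=np.concatenate(
                [np.full(len(s["lam"]), c) for c, s in enumerate(states)]
            ),
            theta=(
                np.concatenate([s["theta"] for s in states]) if store_theta else None
            ),
            meta={
                "chains": chains,
                "iterations": iterations,
                "burn_in": burn_in,
                "thin": thin,
                "seed": seed,
                "acceptance": {
                    k: float(np.mean([s["acc"][k] for s in states]))
                    for k in states[0]["acc"]
                },
            },
        )
        if self.weak_parameters:
            warnings.warn(
                "weakly identified thresholds (never-observed categories): "
                + "; ".join(self.weak_parameters),
                stacklevel=2,
            )
        return GRMResults(self, sample)


def _init_state(data: ItemResponseMatrix, rng):
    n, j = data.scores.shape
    k1 = data.n_categories - 1
    lam = np.full(j, 1.5)
    tau = np.empty((j, k1))
    for jj in range(j):
        vals, _ = data.column(jj)
        for c in range(k1):
            p = np.clip(np.mean(vals >= c + 1), 1e-3, 1 - 1e-3)
            # marginal P(X>=c) ~ expit(-tau/1.5) at lam ~ 2 under a N(0,1) trait
            tau[jj, c] = -1.5 * np.log(p / (1 - p))
        tau[jj] = np.maximum.accumulate(tau[jj])
        tau[jj] += 0.05 * np.arange(k1)  # guarantee strict order
    vals = data.masked()
    srow = vals.mean(axis=1).filled(0.0)
    s = np.asarray(srow, dtype=float)
    sd = s.std()
    theta = (s - s.mean()) / (sd if sd > 0 else 1.0)
    return lam, tau, theta


def _run_chain(data, iterations, burn_in, thin, rng, store_theta=False):
    scores = data.scores
    obs = ~data.missing_mask
    n, j = scores.shape
    k1 = data.n_categories - 1
    lam, tau, theta = _init_state(data, rng)

    loglik = np.empty((n, j))
    for jj in range(j):
        loglik[:, jj] = _column_loglik(lam[jj], tau[jj], theta, scores[:, jj], obs[:, jj])

    s_theta = 0.8
    s_lam = np.full(j, 0.15)
    s_tau = np.full((j, k1), 0.3)
    acc = {"theta": [], "lambda": [], "tau": []}
    window = {"theta": [0, 0], "lambda": [0, 0], "tau": [0, 0]}

    keep_lam, keep_tau, keep_theta = [], [], []

    for it in range(iterations):
        # --- trait updates, all respondents at once
        prop = theta + s_theta * rng.standard_normal(n)
        new_ll = np.empty_like(loglik)
        for jj in range(j):
            new_ll[:, jj] = _column_loglik(
                lam[jj], tau[jj], prop, scores[:, jj], obs[:, jj]
            )
        delta = new_ll.sum(axis=1) - loglik.sum(axis=1)
        delta += 0.5 * (theta**2 - prop**2)  # standard-normal prior
        take = np.log(rng.random(n)) < delta
        theta[take] = prop[take]
        loglik[take] = new_ll[take]
        window["theta"][0] += take.sum()
        window["theta"][1] += n

        # --- discrimination updates (random walk on the log scale)
        for jj in range(j):
            eta = np.log(lam[jj])
            eta_p = eta + s_lam[jj] * rng.standard_normal()
            col = _column_loglik(
                np.exp(eta_p), tau[jj], theta, scores[:, jj], obs[:, jj]
            )
            delta = col.sum() - loglik[:, jj].sum() + 0.5 * (eta**2 - eta_p**2)
            if np.log(rng.random()) < delta:
                lam[jj] = np.exp(eta_p)
                loglik[:, jj] = col
                window["lambda"][0] += 1
            window["lambda"][1] += 1

        # --- threshold updates (order preserved by rejection)
        for jj in range(j):
            for c in range(k1):
                t_p = tau[jj, c] + s_tau[jj, c] * rng.standard_normal()
                lo = tau[jj, c - 1] if c > 0 else -np.inf
                hi = tau[jj, c + 1] if c < k1 - 1 else np.inf
                window["tau"][1] += 1
                if not lo < t_p < hi:
                    continue
                tau_try = tau[jj].copy()
                tau_try[c] = t_p
                col = _column_loglik(
                    lam[jj], tau_try, theta, scores[:, jj], obs[:, jj]
                )
                delta = (
                    col.sum()
                    - loglik[:, jj].sum()
                    + (tau[jj, c] ** 2 - t_p**2) / 200.0
                )
                if np.log(rng.random()) < delta:
                    tau[jj, c] = t_p
                    loglik[:, jj] = col
                    window["tau"][0] += 1

        # --- adapt proposal scales during burn-in
        if it < burn_in and (it + 1) % 50 == 0:
            rate = window["theta"][0] / max(window["theta"][1], 1)
            s_theta *= np.exp(rate - 0.35)
            rate = window["lambda"][0] / max(window["lambda"][1], 1)
            s_lam *= np.exp(rate - 0.35)
            rate = window["tau"][0] / max(window["tau"][1], 1)
            s_tau *= np.exp(rate - 0.35)
            for k in window:
                if it + 1 < burn_in:
                    acc[k].append(window[k][0] / max(window[k][1], 1))
                window[k] = [0, 0]

        if it >= burn_in and (it - burn_in) % thin == 0:
            keep_lam.append(lam.copy())
            keep_tau.append(tau.copy())
            if store_theta:
                keep_theta.append(theta.copy())

    out = {
        "lam": np.array(keep_lam),
        "tau": np.array(keep_tau),
        "acc": {k: window[k][0] / max(window[k][1], 1) for k in window},
    }
    if store_theta:
        out["theta"] = np.array(keep_theta)
    return out


# ----------------------------------------------------------------------
# results


def summarize(sample: PosteriorSample) -> pd.DataFrame:
    """Posterior means, sds, central 95% intervals and split-chain R-hat.

    With a single chain the convergence diagnostic is omitted (NaN) with a
    warning; everything else is computed from the pooled draws.
    """
    arr, names = sample.parameter_array()
    out = pd.DataFrame(index=pd.Index(names, name="parameter"))
    out["mean"] = arr.mean(axis=0)
    out["sd"] = arr.std(axis=0, ddof=1) if len(arr) > 1 else 0.0
    out["hdi_2.5%"] = np.percentile(arr, 2.5, axis=0)
    out["hdi_97.5%"] = np.percentile(arr, 97.5, axis=0)
    if sample.n_chains >= 2:
        out["r_hat"] = _split_rhat(arr, sample.chain_id)
    else:
        warnings.warn("single chain: R-hat omitted", stacklevel=2)
        out["r_hat"] = np.nan
    return out


def _split_rhat(arr: np.ndarray, chain_id: np.ndarray) -> np.ndarray:
    """Split-chain potential scale reduction factor per column of ``arr``."""
    import arviz as az

    chains = np.unique(chain_id)
    m = min(np.sum(chain_id == c) for c in chains)
    stacked = np.stack([arr[chain_id == c][:m] for c in chains])  # (C, m, P)
    return np.asarray(az.rhat(az.convert_to_dataset(stacked))["x"].values)


class GRMResults:
    """Posterior summary of a fitted graded response model.

    Wraps the retained :class:`PosteriorSample`; exposes posterior-mean
    parameters (as a :class:`~gad7irt.model.GRMParameters` usable by every
    scoring/information routine), a summary table, and convergence
    diagnostics.
    """

    def __init__(self, model: GradedResponseModel, sample: PosteriorSample):
        self.model = model
        self.sample = sample
        self._summary: pd.DataFrame | None = None

    def summary_frame(self) -> pd.DataFrame:
        if self._summary is None:
            self._summary = summarize(self.sample)
        return self._summary

    @property
    def rhat_max(self) -> float:
        return float(self.summary_frame()["r_hat"].max())

    def posterior_mean_parameters(self) -> GRMParameters:
        tau = self.sample.thresholds.mean(axis=0)
        # posterior means of ordered draws are ordered; guard regardless
        tau = np.sort(tau, axis=1)
        return GRMParameters(
            discrimination=self.sample.discrimination.mean(axis=0),
            thresholds=tau,
            item_labels=self.model.data.item_labels,
        )

    def summary(self) -> str:
        meta = self.sample.meta
        head = (
            "Graded response model (logistic), Bayesian fit\n"
            f"  respondents: {self.model.data.n_respondents}, "
            f"items: {self.model.data.n_items}\n"
            f"  chains: {meta.get('chains')}, iterations: {meta.get('iterations')}, "
            f"burn-in: {meta.get('burn_in')}, retained draws: {self.sample.n_draws}\n"
        )
        if self.model.weak_parameters:
            head += (
                "  WARNING weakly identified: "
                + "; ".join(self.model.weak_parameters)
                + "\n"
            )
        with pd.option_context("display.float_format", "{:0.3f}".format):
            return head + self.summary_frame().to_string()
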