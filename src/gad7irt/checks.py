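"""Nonparametric unidimensionality checks.

Three necessary conditions implied by any unidimensional monotone latent
variable model for ordered item scores, checked without fitting one:

1. every pairwise item correlation is nonnegative;
2. every conditional item covariance — cov(Xi, Xj) within respondents
   sharing a fixed score on a third item — is nonnegative;
3. the conditional probabilities P(Xi >= c | restscore group) are
   nondecreasing in the restscore.

Each check counts violations; on data from a unidimensional monotone model
the expected count is zero (up to sampling noise controlled by the
``minvi`` slack in check 3).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data import ItemResponseMatrix

__all__ = [
    "CheckReport",
    "check_pairwise_nonnegativity",
    "check_conditional_covariances",
    "check_monotonicity",
    "run_all_checks",
    "default_min_group",
]


@dataclass
class CheckReport:
    """Violation counts for the three unidimensionality criteria."""

    n_negative_pairwise: int = 0
    n_pairs: int = 0
    n_undefined_pairs: int = 0
    n_negative_conditional: int = 0
    n_strata_examined: int = 0
    n_strata_skipped: int = 0
    n_monotonicity_violations: int = 0
    n_monotonicity_comparisons: int = 0
    pairwise_detail: pd.DataFrame | None = None
    conditional_detail: pd.DataFrame | None = None
    monotonicity_detail: pd.DataFrame | None = None
    settings: dict = field(default_factory=dict)

    @property
    def clean(self) -> bool:
        return (
            self.n_negative_pairwise
            + self.n_negative_conditional
            + self.n_monotonicity_violations
        ) == 0

    def to_text(self) -> str:
        return (
            "Unidimensionality checks\n"
            f"  negative pairwise correlations: {self.n_negative_pairwise}"
            f" of {self.n_pairs} pairs"
            f" ({self.n_undefined_pairs} undefined)\n"
            f"  negative conditional covariances: {self.n_negative_conditional}"
            f" of {self.n_strata_examined} strata"
            f" ({self.n_strata_skipped} skipped as too small)\n"
            f"  monotonicity violations: {self.n_monotonicity_violations}"
            f" of {self.n_monotonicity_comparisons} comparisons\n"
            + ("  -> no violations\n" if self.clean else "  -> VIOLATIONS FOUND\n")
        )


def _nan_matrix(data: ItemResponseMatrix) -> np.ndarray:
    vals = data.scores.astype(float)
    vals[data.missing_mask] = np.nan
    return vals


def check_pairwise_nonnegativity(data: ItemResponseMatrix) -> CheckReport:
    """Criterion 1: count item pairs with negative Pearson correlation."""
    vals = _nan_matrix(data)
    j = data.n_items
    rows = []
    neg = undef = 0
    for a in range(j):
        for b in range(a + 1, j):
            ok = ~np.isnan(vals[:, a]) & ~np.isnan(vals[:, b])
            x, y = vals[ok, a], vals[ok, b]
            if ok.sum() < 2 or x.std() == 0 or y.std() == 0:
                r = np.nan
                undef += 1
            else:
                r = float(np.corrcoef(x, y)[0, 1])
                neg += r < 0
            rows.append(
                {"item_i": a + 1, "item_j": b + 1, "r": r, "n": int(ok.sum())}
            )
    return CheckReport(
        n_negative_pairwise=neg,
        n_pairs=j * (j - 1) // 2,
        n_undefined_pairs=undef,
        pairwise_detail=pd.DataFrame(rows),
    )


def check_conditional_covariances(
    data: ItemResponseMatrix, min_stratum: int = 10
) -> CheckReport:
    """Criterion 2: conditional covariances cov(Xi, Xj | Xl = c).

    Iterates over every item pair (i, j), every conditioning item l and
    every observed value c of Xl; strata with fewer than ``min_stratum``
    complete (i, j, l) cases are skipped and reported.
    """
    if data.n_items < 3:
        raise ValueError("conditional covariances need at least 3 items")
    vals = _nan_matrix(data)
    j = data.n_items
    rows = []
    neg = examined = skipped = 0
    for a in range(j):
        for b in range(a + 1, j):
            for l in range(j):
                if l in (a, b):
                    continue
                ok = (
                    ~np.isnan(vals[:, a])
                    & ~np.isnan(vals[:, b])
                    & ~np.isnan(vals[:, l])
                )
                sub = vals[ok][:, [a, b, l]]
                for c in np.unique(sub[:, 2]):
                    stratum = sub[sub[:, 2] == c]
                    if len(stratum) < min_stratum:
                        skipped += 1
                        continue
                    cov = float(np.cov(stratum[:, 0], stratum[:, 1], ddof=1)[0, 1])
                    examined += 1
                    neg += cov < 0
                    rows.append(
                        {
                            "item_i": a + 1,
                            "item_j": b + 1,
                            "conditioner": l + 1,
                            "value": int(c),
                            "cov": cov,
                            "n": len(stratum),
                        }
                    )
    return CheckReport(
        n_negative_conditional=neg,
        n_strata_examined=examined,
        n_strata_skipped=skipped,
        conditional_detail=pd.DataFrame(rows),
        settings={"min_stratum": min_stratum},
    )


def default_min_group(n: int) -> int:
    """Default minimum restscore-group size, following common practice
    for monotonicity checks: N/10 for large samples, N/5 or N/3 for
    moderate and small ones."""
    if n >= 500:
        return n // 10
    if n >= 250:
        return n // 5
    return max(n // 3, 1)


def _restscore_groups(rest: np.ndarray, min_group: int) -> np.ndarray:
    """Merge adjacent restscore values into groups of size >= min_group.

    Returns a group index per respondent; groups are contiguous in the
    restscore ordering and the trailing remainder is merged backwards.
    """
    order_vals, counts = np.unique(rest, return_counts=True)
    group_of_val = np.empty(len(order_vals), dtype=int)
    g = 0
    acc = 0
    for i, cnt in enumerate(counts):
        group_of_val[i] = g
        acc += cnt
        if acc >= min_group:
            g += 1
            acc = 0
    if acc and g > 0:  # fold a small trailing group into its neighbour
        group_of_val[group_of_val == g] = g - 1
    lookup = {v: grp for v, grp in zip(order_vals, group_of_val)}
    return np.array([lookup[v] for v in rest])


def check_monotonicity(
    data: ItemResponseMatrix,
    min_group: int | None = None,
    minvi: float = 0.03,
) -> CheckReport:
    """Criterion 3: monotonicity of P(Xi >= c | restscore group).

    For each item and each cut c, respondents (complete cases) are binned
    by the restscore into contiguous groups of at least ``min_group``; a
    violation is a decrease of more than ``minvi`` between adjacent
    groups. ``minvi=0`` gives the strict count.
    """
    if data.n_items < 3:
        raise ValueError("monotonicity check needs at least 3 items")
    vals = _nan_matrix(data)
    j = data.n_items
    k = data.n_categories
    rows = []
    violations = comparisons = 0
    for a in range(j):
        ok = ~np.isnan(vals).any(axis=1)
        sub = vals[ok]
        if len(sub) == 0:
            continue
        rest = np.delete(sub, a, axis=1).sum(axis=1)
        mg = default_min_group(len(sub)) if min_group is None else min_group
        groups = _restscore_groups(rest, mg)
        n_groups = groups.max() + 1
        for c in range(1, k):
            f = np.array(
                [np.mean(sub[groups == g, a] >= c) for g in range(n_groups)]
            )
            for g in range(n_groups - 1):
                comparisons += 1
                drop = f[g] - f[g + 1]
                if drop > minvi:
                    violations += 1
                    rows.append(
                        {
                            "item": a + 1,
                            "cut": c,
                            "group": g + 1,
                            "f_left": f[g],
                            "f_right": f[g + 1],
                            "decrease": drop,
                        }
                    )
    return CheckReport(
        n_monotonicity_violations=violations,
        n_monotonicity_comparisons=comparisons,
        monotonicity_detail=pd.DataFrame(rows),
        settings={"min_group": min_group, "minvi": minvi},
    )


def run_all_checks(
    data: ItemResponseMatrix,
    min_stratum: int = 10,
    min_group: int | None = None,
    minvi: float = 0.03,
) -> CheckReport:
    """Run all three criteria and merge the counts into one report."""
    r1 = check_pairwise_nonnegativity(data)
    r2 = check_conditional_covariances(data, min_stratum=min_stratum)
    r3 = check_monotonicity(data, min_group=min_group, minvi=minvi)
    return CheckReport(
        n_negative_pairwise=r1.n_negative_pairwise,
        n_pairs=r1.n_pairs,
        n_undefined_pairs=r1.n_undefined_pairs,
        n_negative_conditional=r2.n_negative_conditional,
        n_strata_examined=r2.n_strata_examined,
        n_strata_skipped=r2.n_strata_skipped,
        n_monotonicity_violations=r3.n_monotonicity_violations,
        n_monotonicity_comparisons=r3.n_monotonicity_comparisons,
        pairwise_detail=r1.pairwise_detail,
        conditional_detail=r2.conditional_detail,
        monotonicity_detail=r3.monotonicity_detail,
        settings={"min_stratum": min_stratum, "min_group": min_group, "minvi": minvi},
    )
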