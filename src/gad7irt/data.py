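"""Ordered categorical response matrices.

The universal input of the package: an ``N x J`` matrix of item scores in
``{0, ..., K-1}`` with cell-wise missingness, optional respondent ids and an
optional binary group label (e.g. gender).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ItemResponseMatrix"]


@dataclass
class ItemResponseMatrix:
    """N x J ordered categorical responses with a missingness mask.

    Parameters
    ----------
    scores : ndarray of int, shape (N, J)
        Item scores in ``{0, ..., n_categories - 1}``. Entries under the
        missing mask are ignored (conventionally stored as 0).
    missing_mask : ndarray of bool, shape (N, J)
        True where the response is missing.
    item_labels : list of str, optional
        One label per item; defaults to ``item1..itemJ``.
    group : ndarray of {0, 1} or None
        Optional binary group membership per respondent (NaN allowed for
        unknown); used by the differential-item-functioning scan.
    respondent_id : ndarray or None
        Optional identifiers, carried through to CSV output.
    """

    scores: np.ndarray
    missing_mask: np.ndarray
    item_labels: list[str] = field(default_factory=list)
    group: np.ndarray | None = None
    respondent_id: np.ndarray | None = None
    n_categories: int = 4

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=int)
        self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.scores.ndim != 2:
            raise ValueError("scores must be a 2-d array")
        if self.scores.shape != self.missing_mask.shape:
            raise ValueError("scores and missing_mask shapes differ")
        n, j = self.scores.shape
        if j < 2:
            raise ValueError("need at least two items")
        if not self.item_labels:
            self.item_labels = [f"item{k + 1}" for k in range(j)]
        if len(self.item_labels) != j:
            raise ValueError("item_labels length must equal number of items")
        obs = ~self.missing_mask
        if not obs.any(axis=0).all():
            raise ValueError("every item needs at least one observed response")
        vals = self.scores[obs]
        if vals.size and (vals.min() < 0 or vals.max() >= self.n_categories):
            raise ValueError(
                f"observed scores must lie in 0..{self.n_categories - 1}"
            )
        if self.group is not None:
            self.group = np.asarray(self.group, dtype=float)
            if self.group.shape != (n,):
                raise ValueError("group must have one entry per respondent")

    # ------------------------------------------------------------------
    @property
    def n_respondents(self) -> int:
        return self.scores.shape[0]

    @property
    def n_items(self) -> int:
        return self.scores.shape[1]

    def masked(self) -> np.ma.MaskedArray:
        """Scores as a numpy masked array (mask = missing)."""
        return np.ma.MaskedArray(self.scores, mask=self.missing_mask)

    def column(self, j: int) -> tuple[np.ndarray, np.ndarray]:
        """Observed values and observation indicator of item ``j``."""
        obs = ~self.missing_mask[:, j]
        return self.scores[obs, j], obs

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        item_columns: list[str] | None = None,
        group_column: str | None = "group",
        id_column: str | None = "id",
        n_categories: int = 4,
    ) -> "ItemResponseMatrix":
        """Build from a DataFrame with one column per item.

        ``item_columns`` defaults to every column named ``gad1..gad7`` (or,
        failing that, every column other than the id/group columns). Empty
        cells / NaN mark missing responses.
        """
        if item_columns is None:
            gad = [c for c in frame.columns if c.lower().startswith("gad")]
            if gad:
                item_columns = gad
            else:
                skip = {group_column, id_column}
                item_columns = [c for c in frame.columns if c not in skip]
        raw = frame[item_columns].apply(pd.to_numeric, errors="coerce")
        mask = raw.isna().to_numpy()
        vals = raw.to_numpy(dtype=float)
        bad = (~mask) & ((vals != np.floor(vals)) | (vals < 0) | (vals >= n_categories))
        if bad.any():
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"out-of-range score at row {r}, column {item_columns[c]!r}: {vals[r, c]}"
            )
        scores = np.where(mask, 0, np.nan_to_num(vals)).astype(int)
        group = None
        if group_column and group_column in frame.columns:
            group = pd.to_numeric(frame[group_column], errors="coerce").to_numpy()
        rid = None
        if id_column and id_column in frame.columns:
            rid = frame[id_column].to_numpy()
        return cls(
            scores=scores,
            missing_mask=mask,
            item_labels=list(item_columns),
            group=group,
            respondent_id=rid,
            n_categories=n_categories,
        )

    @classmethod
    def from_csv(cls, path, **kwargs) -> "ItemResponseMatrix":
        frame = pd.read_csv(path)
        if frame.empty:
            raise ValueError(f"{path}: no respondents found")
        return cls.from_dataframe(frame, **kwargs)

    def to_dataframe(self) -> pd.DataFrame:
        data: dict[str, object] = {}
        if self.respondent_id is not None:
            data["id"] = self.respondent_id
        else:
            data["id"] = np.arange(1, self.n_respondents + 1)
        vals = self.scores.astype(float)
        vals[self.missing_mask] = np.nan
        for j, lab in enumerate(self.item_labels):
            data[lab] = vals[:, j]
        if self.group is not None:
            data["group"] = self.group
        return pd.DataFrame(data)

    def to_csv(self, path) -> None:
        """Write as CSV: empty cell = missing, one row per respondent."""
        self.to_dataframe().to_csv(path, index=False, float_format="%.0f")
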