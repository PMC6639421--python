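"""First-order transition records, descriptive count tables and covariate screening.

A daily state series visits the states dose-missing (0) and dose-taking (1);
between adjacent days four transitions are possible: [01], [11], [10], [00]
(written previous-state then current-state).  The previous state of each
subject's first observed day is taken to be 1 ("dose taken"), justified by
high overall adherence and the limited sensitivity of the model to this
assumption; the default is overridable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .io_events import AdherenceSeries

TRANSITION_ORDER = ("11", "10", "01", "00")  # display order of count tables


@dataclass(frozen=True)
class TransitionCounts:
    """Counts of the four first-order transitions."""

    n01: int = 0
    n11: int = 0
    n10: int = 0
    n00: int = 0

    @property
    def total(self) -> int:
        return self.n01 + self.n11 + self.n10 + self.n00

    def __add__(self, other: "TransitionCounts") -> "TransitionCounts":
        return TransitionCounts(self.n01 + other.n01, self.n11 + other.n11,
                                self.n10 + other.n10, self.n00 + other.n00)

    def as_dict(self) -> dict[str, int]:
        return {"11": self.n11, "10": self.n10, "01": self.n01, "00": self.n00}

    def share(self, kind: str) -> float:
        """Fraction of this group's transitions that are of the given kind."""
        tot = self.total
        return self.as_dict()[kind] / tot if tot else float("nan")


def build_transitions(
    series: AdherenceSeries,
    covariates: pd.DataFrame | None = None,
    *,
    initial_state: int = 1,
) -> pd.DataFrame:
    """One transition record per observed day of a series.

    Record *k* (1-based ``day_index``) carries ``prev_state`` = state of day
    k-1 (``initial_state`` for day 1) and ``state`` = state of day k, plus the
    day's covariate vector if given.

    Returns a DataFrame with columns ``subject_id, day_index, prev_state,
    state`` followed by the covariate columns.
    """
    if initial_state not in (0, 1):
        raise ConfigurationError("initial_state must be 0 or 1")
    states = series.states
    n = len(states)
    prev = np.empty(n, dtype=np.int8)
    prev[0] = initial_state
    prev[1:] = states[:-1]
    rec = pd.DataFrame({
        "subject_id": series.subject_id,
        "day_index": np.arange(1, n + 1),
        "prev_state": prev,
        "state": states,
    })
    if covariates is not None:
        if len(covariates) != n:
            raise DataError(
                f"subject {series.subject_id!r}: {len(covariates)} covariate "
                f"rows for {n} days")
        for c in covariates.columns:
            rec[c] = np.asarray(covariates[c], dtype=float)
    return rec


def count_transitions(
    records: pd.DataFrame,
    group_by: str | None = None,
) -> TransitionCounts | dict:
    """Count the four transitions, optionally within categories of a column.

    With ``group_by`` the return value maps each observed category value to
    its :class:`TransitionCounts`.
    """
    def _count(df: pd.DataFrame) -> TransitionCounts:
        if not len(df):
            return TransitionCounts()
        code = 2 * df["prev_state"].to_numpy() + df["state"].to_numpy()
        n = np.bincount(code, minlength=4)  # 0->[00],1->[01],2->[10],3->[11]
        return TransitionCounts(n01=int(n[1]), n11=int(n[3]),
                                n10=int(n[2]), n00=int(n[0]))

    if group_by is None:
        return _count(records)
    if group_by not in records.columns:
        raise ConfigurationError(f"unknown grouping covariate {group_by!r}")
    return {cat: _count(grp) for cat, grp in records.groupby(group_by, sort=True)}


def counts_table(observed: TransitionCounts, **named: TransitionCounts) -> pd.DataFrame:
    """Count table with rows [11],[10],[01],[00] and one column per argument."""
    data = {"observed": observed.as_dict(), **{k: v.as_dict() for k, v in named.items()}}
    return pd.DataFrame(data, index=list(TRANSITION_ORDER)).rename_axis("transition")


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of the sparse-transition screen for one covariate."""

    covariate: str
    keep: bool
    reasons: tuple[str, ...] = ()


def screen_covariates(
    records: pd.DataFrame,
    covariate_names: list[str],
    *,
    threshold: float = 0.05,
    pooled: bool = False,
) -> dict[str, ScreenResult]:
    """Flag covariates whose transition support is too sparse to model.

    A covariate is dropped when, within any one of its categories, any of the
    four transition types accounts for strictly less than ``threshold``
    (default 5%) of that category's transitions; a share of exactly the
    threshold is retained.  A category with zero transitions is flagged
    explicitly.  ``pooled=True`` instead evaluates the rule on the covariate's
    transitions pooled across categories (an alternative reading of the rule;
    the within-category form is the default).
    """
    out: dict[str, ScreenResult] = {}
    for cov in covariate_names:
        per_cat = count_transitions(records, group_by=cov)
        reasons: list[str] = []
        if pooled:
            per_cat = {"pooled": sum(per_cat.values(), TransitionCounts())}
        for cat, counts in per_cat.items():
            if counts.total == 0:
                reasons.append(f"category {cat!r}: no transitions")
                continue
            for kind in TRANSITION_ORDER:
                share = counts.share(kind)
                if share < threshold:
                    reasons.append(
                        f"category {cat!r}: [{kind}] share "
                        f"{share:.3%} < {threshold:.0%}")
        out[cov] = ScreenResult(cov, keep=not reasons, reasons=tuple(reasons))
    return out


# ---------------------------------------------------------------------------
# Stacked dataset feeding the likelihood
# ---------------------------------------------------------------------------

@dataclass
class TransitionDataset:
    """All subjects' transition records stacked into likelihood-ready arrays.

    Attributes
    ----------
    subject_ids : array of the distinct subject identifiers (fit order).
    subj : int codes into ``subject_ids``, one per record.
    prev, state : record-level previous/current states.
    X : (n_records, n_covariates) float design of raw covariate columns.
    covariate_names : column order of ``X``.
    """

    subject_ids: np.ndarray
    subj: np.ndarray
    prev: np.ndarray
    state: np.ndarray
    X: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_records(self) -> int:
        return len(self.state)

    def frame(self) -> pd.DataFrame:
        df = pd.DataFrame({
            "subject_id": self.subject_ids[self.subj],
            "prev_state": self.prev,
            "state": self.state,
        })
        for j, c in enumerate(self.covariate_names):
            df[c] = self.X[:, j]
        return df

    def column(self, name: str) -> np.ndarray:
        try:
            j = self.covariate_names.index(name)
        except ValueError:
            raise ConfigurationError(
                f"covariate {name!r} not in dataset "
                f"(have {self.covariate_names})") from None
        return self.X[:, j]

    @classmethod
    def from_records(cls, records: pd.DataFrame,
                     covariate_names: list[str] | None = None) -> "TransitionDataset":
        if covariate_names is None:
            covariate_names = [c for c in records.columns
                               if c not in ("subject_id", "day_index",
                                            "prev_state", "state")]
        missing = set(covariate_names) - set(records.columns)
        if missing:
            raise ConfigurationError(f"records lack covariate column(s) {sorted(missing)}")
        ids, subj = np.unique(records["subject_id"].to_numpy(), return_inverse=True)
        X = (records[covariate_names].to_numpy(dtype=float)
             if covariate_names else np.empty((len(records), 0)))
        return cls(
            subject_ids=ids,
            subj=subj.astype(np.int64),
            prev=records["prev_state"].to_numpy(dtype=np.int8),
            state=records["state"].to_numpy(dtype=np.int8),
            X=X,
            covariate_names=list(covariate_names),
        )

    @classmethod
    def from_series(cls, series_list, covariate_frames=None, *,
                    initial_state: int = 1) -> "TransitionDataset":
        """Build directly from AdherenceSeries plus per-day covariate frames."""
        frames = []
        for i, s in enumerate(series_list):
            cov = None if covariate_frames is None else covariate_frames[i]
            frames.append(build_transitions(s, cov, initial_state=initial_state))
        records = pd.concat(frames, ignore_index=True)
        return cls.from_records(records)
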