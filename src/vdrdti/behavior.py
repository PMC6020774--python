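"""Scoring of value-directed remembering lists.

In a value-directed remembering task, each studied word carries a point
value; participants maximize their score by prioritizing high-value words.
Performance is summarized per list by the points actually earned ("actual
score"), the points expected if values had been assigned at random to the
recalled words ("chance score" = mean list value x number recalled), and the
best possible score for that many recalled words ("ideal score").  The
Selectivity Index,

    SI = (actual - chance) / (ideal - chance),

is 1 for perfectly value-prioritized recall, 0 for value-insensitive recall,
and negative when low-value words are preferentially recalled.  SI is
undefined when ideal == chance (nothing recalled, or the whole list
recalled).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "StudyDesign",
    "RecallRecord",
    "ListScore",
    "SubjectSummary",
    "score_list",
    "selectivity_index",
    "subject_summary",
    "paired_t",
    "one_sample_t",
    "read_behavior_tsv",
    "write_summary_tsv",
    "UndefinedSelectivityError",
]


class UndefinedSelectivityError(ValueError):
    """Selectivity Index requested where ideal score equals chance score."""


@dataclass(frozen=True)
class StudyDesign:
    """Task design: lists of words with high and low point values.

    The default is the standard design: 5 scored lists of 24 words each,
    12 high-value words (10, 11 or 12 points, four of each) and 12
    low-value words (1, 2 or 3 points, four of each).
    """

    n_lists: int = 5
    words_per_list: int = 24
    high_values: tuple[int, ...] = (10, 11, 12)
    low_values: tuple[int, ...] = (1, 2, 3)
    n_high_per_list: int = 12
    n_low_per_list: int = 12

    def __post_init__(self) -> None:
        if self.n_high_per_list + self.n_low_per_list != self.words_per_list:
            raise ValueError("n_high + n_low must equal words_per_list")
        if min(self.high_values) <= max(self.low_values):
            raise ValueError("every high value must exceed every low value")
        if self.n_high_per_list % len(self.high_values) or self.n_low_per_list % len(self.low_values):
            raise ValueError("value sets must tile the high/low halves evenly")

    def list_values(self) -> np.ndarray:
        """Point values of one list (high block then low block)."""
        high = np.repeat(self.high_values, self.n_high_per_list // len(self.high_values))
        low = np.repeat(self.low_values, self.n_low_per_list // len(self.low_values))
        return np.concatenate([high, low]).astype(float)

    @property
    def mean_value(self) -> float:
        return float(self.list_values().mean())

    def is_high(self, values: np.ndarray) -> np.ndarray:
        return np.isin(values, self.high_values)


@dataclass
class RecallRecord:
    """One studied list: per-word point values and recall outcomes."""

    list_values: np.ndarray  # point value of each studied word
    recalled: np.ndarray  # boolean, same length

    def __post_init__(self) -> None:
        self.list_values = np.asarray(self.list_values, dtype=float)
        self.recalled = np.asarray(self.recalled, dtype=bool)
        if self.list_values.ndim != 1 or self.list_values.size == 0:
            raise ValueError("a recall record needs at least one studied word")
        if self.recalled.shape != self.list_values.shape:
            raise ValueError("recalled must align with list_values")


@dataclass(frozen=True)
class ListScore:
    actual: float
    chance: float
    ideal: float
    n_recalled: int
    n_high_recalled: int
    n_low_recalled: int
    selectivity: Optional[float]  # None when ideal == chance


@dataclass(frozen=True)
class SubjectSummary:
    mean_high_recall: float
    mean_low_recall: float
    mean_selectivity: Optional[float]
    n_lists_scored: int


def score_list(record: RecallRecord, design: StudyDesign | None = None) -> ListScore:
    """Score one list: actual/chance/ideal points and Selectivity Index.

    ``chance`` uses the mean point value of the full studied list;
    ``ideal`` sums the n_recalled largest list values.  Selectivity is
    ``None`` when ideal == chance (zero or full recall).
    """
    design = design or StudyDesign()
    values = record.list_values
    recalled = record.recalled
    n_recalled = int(recalled.sum())
    actual = float(values[recalled].sum())
    chance = float(values.mean()) * n_recalled
    ideal = float(np.sort(values)[::-1][:n_recalled].sum())
    high = design.is_high(values)
    sel = None
    if not np.isclose(ideal, chance):
        sel = (actual - chance) / (ideal - chance)
    return ListScore(
        actual=actual,
        chance=chance,
        ideal=ideal,
        n_recalled=n_recalled,
        n_high_recalled=int((recalled & high).sum()),
        n_low_recalled=int((recalled & ~high).sum()),
        selectivity=sel,
    )


def selectivity_index(score: ListScore) -> float:
    """Selectivity Index of a scored list; raises when undefined."""
    if score.selectivity is None:
        raise UndefinedSelectivityError(
            "ideal score equals chance score (zero or full recall); "
            "the Selectivity Index is undefined for this list"
        )
    return score.selectivity


def subject_summary(
    records: Sequence[RecallRecord], design: StudyDesign | None = None
) -> SubjectSummary:
    """Average list scores across a subject's lists.

    Lists with undefined selectivity (zero or full recall) are excluded
    from the selectivity mean only; recall-count means use every list.
    """
    if len(records) == 0:
        raise ValueError("need at least one list")
    design = design or StudyDesign()
    scores = [score_list(r, design) for r in records]
    sels = [s.selectivity for s in scores if s.selectivity is not None]
    return SubjectSummary(
        mean_high_recall=float(np.mean([s.n_high_recalled for s in scores])),
        mean_low_recall=float(np.mean([s.n_low_recalled for s in scores])),
        mean_selectivity=float(np.mean(sels)) if sels else None,
        n_lists_scored=len(scores),
    )


def _t_from_diffs(d: np.ndarray) -> tuple[float, int, float]:
    n = d.size
    if n < 2:
        raise ValueError("need n >= 2")
    sd = d.std(ddof=1)
    if sd == 0:
        # zero-variance differences: signal with an infinite (or nan) t
        m = d.mean()
        t = float(np.inf * np.sign(m)) if m != 0 else float("nan")
        p = 0.0 if np.isfinite(m) and m != 0 else float("nan")
        return t, n - 1, p
    t = float(d.mean() / (sd / np.sqrt(n)))
    p = float(2 * sps.t.sf(abs(t), n - 1))
    return t, n - 1, p


def paired_t(x: Sequence[float], y: Sequence[float]) -> tuple[float, int, float]:
    """Paired t-test; returns (t, df, two-tailed p) with df = n - 1."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    return _t_from_diffs(x - y)


def one_sample_t(x: Sequence[float], mu0: float = 0.0) -> tuple[float, int, float]:
    """One-sample t-test against ``mu0``; returns (t, df, two-tailed p)."""
    return _t_from_diffs(np.asarray(x, float) - mu0)


# ---------------------------------------------------------------------------
# TSV interfaces

BEHAVIOR_COLUMNS = ["subject_id", "list_id", "word_idx", "value", "recalled"]


def read_behavior_tsv(
    path, design: StudyDesign | None = None
) -> dict[str, list[RecallRecord]]:
    """Read a trial table (subject_id, list_id, word_idx, value, recalled).

    Returns per-subject lists of :class:`RecallRecord`, validated against
    the design's value sets and list length.
    """
    design = design or StudyDesign()
    df = pd.read_csv(path, sep="\t")
    missing = set(BEHAVIOR_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"behavior TSV missing columns: {sorted(missing)}")
    allowed = set(design.high_values) | set(design.low_values)
    if not set(df["value"].unique()) <= allowed:
        raise ValueError("behavior TSV contains values outside the design's value sets")
    out: dict[str, list[RecallRecord]] = {}
    for (subj, _lst), grp in df.groupby(["subject_id", "list_id"], sort=True):
        grp = grp.sort_values("word_idx")
        if len(grp) != design.words_per_list:
            raise ValueError(
                f"subject {subj}: list has {len(grp)} words, expected {design.words_per_list}"
            )
        out.setdefault(str(subj), []).append(
            RecallRecord(grp["value"].to_numpy(float), grp["recalled"].to_numpy(bool))
        )
    return out


def write_summary_tsv(path, summaries: dict[str, SubjectSummary]) -> None:
    rows = [
        {
            "subject_id": sid,
            "mean_high_recall": s.mean_high_recall,
            "mean_low_recall": s.mean_low_recall,
            "mean_selectivity": np.nan if s.mean_selectivity is None else s.mean_selectivity,
        }
        for sid, s in summaries.items()
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
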