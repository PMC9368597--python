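"""Model-ready feature records and leakage-safe worker-level splits.

Two prediction scenarios share one feature table: (i) weeks until the next
medical appointment, and (ii) the next appointment's per-body-part severity.
Each record pairs an appointment's 14 severity scores and encoded worker
attributes (area, function, work schedule, gender, seniority) with the
targets observed at the *following* appointment, so a worker with n
appointments contributes n-1 records and single-appointment workers
contribute none. The final appointment of a timeline has no successor and is
simply dropped (no survival modelling).

Splitting and cross-validation folds group by worker: records of one worker
never appear on both sides of a split or in two folds, which would otherwise
leak a worker's own history from train to test.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path

import numpy as np
import pandas as pd

from .bodyparts import PART_NAMES

__all__ = [
    "DataError",
    "SplitError",
    "FeatureTable",
    "SplitPlan",
    "CategoricalVocabulary",
    "assemble_features",
    "split_by_worker",
    "make_folds",
]

CATEGORICALS = ("area", "function", "schedule", "gender")
FEATURE_COLUMNS = tuple(PART_NAMES) + tuple(f"{c}_code" for c in CATEGORICALS) + ("seniority_years",)
TARGET_INTERVAL = "target_interval_weeks"
NEXT_SCORE_COLUMNS = tuple(f"next_{p}" for p in PART_NAMES)


class DataError(ValueError):
    pass


class SplitError(ValueError):
    pass


@dataclass
class CategoricalVocabulary:
    """Stable integer codes for categorical worker attributes.

    Codes are assigned by sorted level order and persisted alongside the
    feature table so that models and explanations agree on the encoding
    across runs.
    """

    levels: dict[str, list[str]] = field(default_factory=dict)

    @classmethod
    def fit(cls, frame: pd.DataFrame) -> "CategoricalVocabulary":
        return cls({c: sorted(frame[c].astype(str).unique()) for c in CATEGORICALS})

    def encode(self, column: str, values: pd.Series) -> pd.Series:
        table = {lvl: i for i, lvl in enumerate(self.levels[column])}
        return values.astype(str).map(lambda v: table.get(v, -1)).astype(int)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.levels, indent=1), encoding="utf-8")

    @classmethod
    def load(cls, path: str | Path) -> "CategoricalVocabulary":
        return cls(json.loads(Path(path).read_text(encoding="utf-8")))


@dataclass
class FeatureTable:
    """Feature records plus the vocabulary that encoded them."""

    frame: pd.DataFrame
    vocabulary: CategoricalVocabulary

    @property
    def X(self) -> np.ndarray:
        return self.frame[list(FEATURE_COLUMNS)].to_numpy(dtype=float)

    def y_interval(self) -> np.ndarray:
        return self.frame[TARGET_INTERVAL].to_numpy(dtype=float)

    def y_next_score(self, part: str) -> np.ndarray:
        return self.frame[f"next_{part}"].to_numpy(dtype=float)

    @property
    def workers(self) -> np.ndarray:
        return self.frame["worker_id"].to_numpy()


def _round_half_up_weeks(days: int) -> int:
    return int(np.floor(days / 7 + 0.5))


def assemble_features(score_frame: pd.DataFrame) -> FeatureTable:
    """Build feature records from a per-appointment score table.

    ``score_frame`` is the scoring stage output: one row per appointment
    with worker_id, date, area/function/schedule/gender/seniority_years and
    the 14 per-part scores. Rows are paired with each worker's next
    appointment; the interval target is whole weeks between consecutive
    dates (days/7, rounded half-up). Non-monotone dates within a worker
    raise a :class:`DataError` naming the worker.
    """
    vocab = CategoricalVocabulary.fit(score_frame)
    frame = score_frame.copy()
    frame["_date"] = pd.to_datetime(frame["date"])

    records = []
    for worker_id, grp in frame.groupby("worker_id", sort=True):
        grp = grp.reset_index(drop=True)
        dates = grp["_date"].tolist()
        if any(b < a for a, b in zip(dates, dates[1:])):
            raise DataError(f"non-monotone appointment dates for worker {worker_id!r}")
        if len(grp) < 2:
            continue  # single-appointment workers contribute no records
        for i in range(len(grp) - 1):
            cur, nxt = grp.iloc[i], grp.iloc[i + 1]
            rec = {"worker_id": worker_id, "date": cur["date"]}
            for p in PART_NAMES:
                rec[p] = float(cur[p])
            for c in CATEGORICALS:
                rec[c] = cur[c]
            rec["seniority_years"] = float(cur["seniority_years"])
            days = int((nxt["_date"] - cur["_date"]).days)
            rec[TARGET_INTERVAL] = _round_half_up_weeks(days)
            for p in PART_NAMES:
                rec[f"next_{p}"] = float(nxt[p])
            records.append(rec)

    out = pd.DataFrame(records)
    if len(out):
        for c in CATEGORICALS:
            out[f"{c}_code"] = vocab.encode(c, out[c])
    else:
        out = pd.DataFrame(
            columns=["worker_id", "date", *PART_NAMES, *CATEGORICALS, "seniority_years",
                     TARGET_INTERVAL, *NEXT_SCORE_COLUMNS, *(f"{c}_code" for c in CATEGORICALS)]
        )
    return FeatureTable(out, vocab)


@dataclass
class SplitPlan:
    """Worker-disjoint train/test assignment with CV folds over train."""

    train_index: list
    test_index: list
    folds: list  # list of lists of record indices (worker-disjoint)
    seed: int

    def save(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                {
                    "seed": self.seed,
                    "train_index": [int(i) for i in self.train_index],
                    "test_index": [int(i) for i in self.test_index],
                    "folds": [[int(i) for i in f] for f in self.folds],
                },
                indent=1,
            ),
            encoding="utf-8",
        )

    @classmethod
    def load(cls, path: str | Path) -> "SplitPlan":
        d = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(d["train_index"], d["test_index"], d["folds"], d["seed"])


def split_by_worker(
    table: FeatureTable | pd.DataFrame,
    test_fraction: float = 0.2,
    seed: int = 0,
    k_folds: int = 0,
) -> SplitPlan:
    """Split records into train/test on workers, not records.

    Workers are shuffled deterministically by seed and assigned to the test
    side until its record count first reaches the target fraction, keeping
    the realised record fraction within one worker's appointments of the
    target. Optionally builds ``k_folds`` worker-disjoint CV folds on train.
    """
    frame = table.frame if isinstance(table, FeatureTable) else table
    workers = frame["worker_id"].to_numpy()
    uniq = np.unique(workers)
    if len(uniq) < 2:
        raise SplitError("need at least 2 distinct workers to split")
    if not 0 <= test_fraction < 1:
        raise SplitError("test_fraction must be in [0, 1)")
    if test_fraction == 0:
        warnings.warn("test_fraction 0: empty test set", stacklevel=2)

    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    counts = frame.groupby("worker_id").size()
    target = test_fraction * len(frame)
    test_workers: set = set()
    got = 0
    for w in order:
        if got >= target:
            break
        test_workers.add(w)
        got += int(counts[w])

    idx = np.arange(len(frame))
    is_test = np.isin(workers, sorted(test_workers))
    train_index = [int(i) for i in idx[~is_test]]
    test_index = [int(i) for i in idx[is_test]]

    folds: list[list[int]] = []
    if k_folds:
        folds = make_folds(frame.iloc[train_index], k_folds, seed, base_index=train_index)
    return SplitPlan(train_index, test_index, folds, seed)


def make_folds(
    train_frame: pd.DataFrame, k: int, seed: int = 0, base_index: list | None = None
) -> list[list[int]]:
    """Worker-disjoint folds of near-equal record counts over the train set.

    Workers are shuffled by seed, then assigned greedily (largest record
    count first) to the currently smallest fold; ties keep shuffle order.
    """
    if k < 2:
        raise SplitError("need k >= 2 folds (k=1 leaves no held-out fold)")
    workers = train_frame["worker_id"].to_numpy()
    uniq = list(np.unique(workers))
    if k > len(uniq):
        raise SplitError(f"k={k} folds but only {len(uniq)} distinct workers")
    base = list(base_index) if base_index is not None else list(range(len(train_frame)))

    rng = np.random.default_rng(seed)
    order = list(rng.permutation(uniq))
    counts = train_frame.groupby("worker_id").size()
    order.sort(key=lambda w: -int(counts[w]))  # stable: keeps shuffle order on ties

    fold_of: dict = {}
    sizes = [0] * k
    for w in order:
        f = int(np.argmin(sizes))
        fold_of[w] = f
        sizes[f] += int(counts[w])

    folds: list[list[int]] = [[] for _ in range(k)]
    for pos, w in enumerate(workers):
        folds[fold_of[w]].append(base[pos])
    return folds
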