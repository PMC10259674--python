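"""Examination data model, long-format CSV I/O, reliability filtering, pairing.

An :class:`Exam` is one eye's single microperimetry test: a threshold in dB
for every grid locus plus reliability metadata.  Thresholds live in
{-1.0} ∪ [0.0, 36.0]; -1.0 is the device's arbitrary code for a non-seen
stimulus at maximum intensity.  Differences between paired exams are taken
on the raw thresholds, so a -1.0 dB -> 6.0 dB change counts as a +7.0 dB
gain — the convention used when scoring pointwise endpoints.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .grid import Grid

log = logging.getLogger(__name__)

NON_SEEN_DB = -1.0
MAX_DB = 36.0

#: exams with fixation losses at or above this percentage are unreliable
DEFAULT_MAX_FIXATION_LOSS_PCT = 30.0

CSV_COLUMNS = [
    "patient_id", "eye", "visit", "test_index", "locus_id",
    "x_deg", "y_deg", "threshold_db", "fixation_loss_pct", "duration_s",
]


class ExamValidationError(ValueError):
    """Raised when an exam table violates the threshold or grid contract."""


@dataclass(frozen=True)
class Exam:
    patient_id: str
    eye: str  # "right" | "left"
    visit: int
    test_index: int
    thresholds_db: Mapping[int, float]
    fixation_loss_pct: float = 0.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        for lid, t in self.thresholds_db.items():
            if not (t == NON_SEEN_DB or 0.0 <= t <= MAX_DB):
                raise ExamValidationError(
                    f"threshold {t} at locus {lid} outside {{-1.0}} ∪ [0.0, 36.0]"
                )

    @property
    def key(self) -> tuple:
        return (self.patient_id, self.eye, self.visit, self.test_index)

    def values(self, grid: Grid | None = None,
               locus_ids: Sequence[int] | None = None) -> np.ndarray:
        """Thresholds as an array, in grid order (or a given locus subset)."""
        if locus_ids is None:
            locus_ids = grid.locus_ids if grid is not None else sorted(self.thresholds_db)
        return np.array([self.thresholds_db[lid] for lid in locus_ids], dtype=float)


@dataclass(frozen=True)
class TestPair:
    """Two aligned exams of one eye with per-locus raw differences (b - a)."""

    exam_a: Exam
    exam_b: Exam
    differences_db: Mapping[int, float]

    @property
    def patient_id(self) -> str:
        return self.exam_a.patient_id

    @property
    def eye(self) -> str:
        return self.exam_a.eye

    def diff_values(self, locus_ids: Sequence[int] | None = None) -> np.ndarray:
        if locus_ids is None:
            locus_ids = sorted(self.differences_db)
        return np.array([self.differences_db[lid] for lid in locus_ids], dtype=float)

    def reversed(self) -> "TestPair":
        return TestPair(self.exam_b, self.exam_a,
                        {lid: -d for lid, d in self.differences_db.items()})


def pair_exams(exam_a: Exam, exam_b: Exam) -> TestPair:
    if set(exam_a.thresholds_db) != set(exam_b.thresholds_db):
        raise ExamValidationError("paired exams cover different loci")
    diffs = {lid: exam_b.thresholds_db[lid] - exam_a.thresholds_db[lid]
             for lid in exam_a.thresholds_db}
    return TestPair(exam_a, exam_b, diffs)


def exams_to_frame(exams: Iterable[Exam], grid: Grid) -> pd.DataFrame:
    coords = {l.locus_id: (l.x_deg, l.y_deg) for l in grid.loci}
    rows = []
    for ex in exams:
        for lid in grid.locus_ids:
            x, y = coords[lid]
            rows.append((ex.patient_id, ex.eye, ex.visit, ex.test_index, lid,
                         x, y, ex.thresholds_db[lid], ex.fixation_loss_pct,
                         ex.duration_s))
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def save_exams(exams: Iterable[Exam], grid: Grid, path) -> None:
    exams_to_frame(exams, grid).to_csv(path, index=False)


def exams_from_frame(df: pd.DataFrame, grid: Grid) -> list[Exam]:
    required = {"patient_id", "eye", "visit", "test_index", "locus_id", "threshold_db"}
    missing = required - set(df.columns)
    if missing:
        raise ExamValidationError(f"missing columns: {sorted(missing)}")

    bad = df[~((df["threshold_db"] == NON_SEEN_DB)
               | ((df["threshold_db"] >= 0.0) & (df["threshold_db"] <= MAX_DB)))]
    if len(bad):
        rows = (bad.index + 2).tolist()[:10]  # 1-based, after header
        raise ExamValidationError(
            f"thresholds outside {{-1.0}} ∪ [0.0, 36.0] at file rows {rows}"
        )

    key_cols = ["patient_id", "eye", "visit", "test_index"]
    dup = df.duplicated(subset=key_cols + ["locus_id"], keep=False)
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:10]
        raise ExamValidationError(f"duplicate (patient,eye,visit,test,locus) rows: {rows}")

    want = set(grid.locus_ids)
    exams = []
    for key, g in df.groupby(key_cols, sort=True):
        got = set(g["locus_id"].astype(int))
        if got != want:
            miss, extra = sorted(want - got), sorted(got - want)
            raise ExamValidationError(
                f"exam {key}: missing loci {miss[:10]}, unexpected loci {extra[:10]}"
            )
        thresholds = dict(zip(g["locus_id"].astype(int), g["threshold_db"].astype(float)))
        fl = float(g["fixation_loss_pct"].iloc[0]) if "fixation_loss_pct" in g else 0.0
        dur = None
        if "duration_s" in g and not pd.isna(g["duration_s"].iloc[0]):
            dur = float(g["duration_s"].iloc[0])
        exams.append(Exam(patient_id=str(key[0]), eye=str(key[1]), visit=int(key[2]),
                          test_index=int(key[3]), thresholds_db=thresholds,
                          fixation_loss_pct=fl, duration_s=dur))
    return exams


def load_exams(path, grid: Grid) -> list[Exam]:
    """Read exams from long-format CSV, validating against the grid."""
    return exams_from_frame(pd.read_csv(path), grid)


def filter_reliable(
    exams: Iterable[Exam],
    max_fixation_loss_pct: float = DEFAULT_MAX_FIXATION_LOSS_PCT,
) -> tuple[list[Exam], list[Exam]]:
    """Split exams into (kept, excluded) by the fixation-loss criterion.

    Exams with fixation losses at or above the cutoff are unreliable and
    excluded.  Exclusion is per-exam: the fellow eye of an excluded exam is
    retained if it is itself reliable.  An exam at exactly the cutoff is
    excluded, with a warning, since the boundary is ambiguous in common
    clinical phrasing ("30% or greater" excluded vs "30% or less" included).
    """
    kept, excluded = [], []
    for ex in exams:
        if ex.fixation_loss_pct >= max_fixation_loss_pct:
            if ex.fixation_loss_pct == max_fixation_loss_pct:
                log.warning(
                    "exam %s at exactly %.1f%% fixation losses: excluded "
                    "(boundary case)", ex.key, max_fixation_loss_pct,
                )
            excluded.append(ex)
        else:
            kept.append(ex)
    return kept, excluded


def make_pairs(exams: Iterable[Exam], pairing: str = "test2_vs_test3") -> list[TestPair]:
    """Form aligned TestPairs per (patient, eye).

    ``test2_vs_test3``
        From triplicate same-visit testing: test 1 is a learning test and
        dropped; the pair is (test 2, test 3).
    ``visit1_vs_visit2``
        Longitudinal: the pair is (visit 1, visit 2) single tests.

    Unpaired exams are skipped with a logged warning.
    """
    by_eye: dict[tuple, list[Exam]] = {}
    for ex in exams:
        by_eye.setdefault((ex.patient_id, ex.eye), []).append(ex)

    pairs: list[TestPair] = []
    for key, group in sorted(by_eye.items()):
        if pairing == "test2_vs_test3":
            lut = {ex.test_index: ex for ex in group}
            a, b = lut.get(2), lut.get(3)
        elif pairing == "visit1_vs_visit2":
            lut = {ex.visit: ex for ex in group}
            a, b = lut.get(1), lut.get(2)
        else:
            raise ValueError(f"unknown pairing {pairing!r}")
        if a is None or b is None:
            log.warning("unpaired exams for %s under %s: skipped", key, pairing)
            continue
        pairs.append(pair_exams(a, b))
    return pairs
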