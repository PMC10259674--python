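"""The three retinal-sensitivity indices: pointwise, mean and volume.

Pointwise sensitivity is the raw per-locus threshold.  Mean sensitivity
(MS) averages the raw thresholds — non-seen loci enter as -1.0 dB — and is
then clamped below at 0.0 dB, emulating the device floor; with many
non-seen loci MS is driven to 0.0 even when residual islands of vision
remain.  Volume sensitivity instead remaps -1.0 -> 0.0 dB and just-seen
0.0 -> 0.1 dB, then takes the area-weighted sum over the grid (dB·deg²);
it returns zero only when every locus is truly non-seen, which is why it
resists the floor effect that compresses MS in late disease.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exams import Exam, NON_SEEN_DB
from .grid import Grid

#: nominal dB assigned to just-seen (0.0 dB) loci in the volume remap
JUST_SEEN_REMAP_DB = 0.1


class NoSeenLociError(ValueError):
    """Raised when a seen-only summary is requested of an all-non-seen exam."""


@dataclass(frozen=True)
class IndexResult:
    patient_id: str
    eye: str
    visit: int
    test_index: int
    mean_sensitivity_db: float
    raw_mean_db: float
    volume_sensitivity_db_deg2: float
    n_nonseen: int
    n_just_seen: int
    median_seen_db: float | None


def mean_sensitivity(exam: Exam, clamp: bool = True) -> float:
    """Mean of raw thresholds over all loci, floored at 0.0 dB by default."""
    m = float(np.mean(exam.values()))
    return max(m, 0.0) if clamp else m


def volume_sensitivity(exam: Exam, grid: Grid) -> float:
    """Area-weighted sum of remapped thresholds, in dB·deg²."""
    vals = exam.values(grid)
    remapped = np.where(vals == NON_SEEN_DB, 0.0,
                        np.where(vals == 0.0, JUST_SEEN_REMAP_DB, vals))
    areas = np.array([grid.areas_deg2[lid] for lid in grid.locus_ids])
    return float(np.sum(remapped * areas))


def median_seen(exam: Exam) -> float:
    """Median threshold over seen loci (> -1.0 dB); just-seen 0.0 counts as seen."""
    vals = exam.values()
    seen = vals[vals > NON_SEEN_DB]
    if seen.size == 0:
        raise NoSeenLociError("no seen loci: median of seen points undefined")
    return float(np.median(seen))


def index_summary(exam: Exam, grid: Grid) -> IndexResult:
    vals = exam.values(grid)
    try:
        med = median_seen(exam)
    except NoSeenLociError:
        med = None
    return IndexResult(
        patient_id=exam.patient_id,
        eye=exam.eye,
        visit=exam.visit,
        test_index=exam.test_index,
        mean_sensitivity_db=mean_sensitivity(exam),
        raw_mean_db=mean_sensitivity(exam, clamp=False),
        volume_sensitivity_db_deg2=volume_sensitivity(exam, grid),
        n_nonseen=int(np.sum(vals == NON_SEEN_DB)),
        n_just_seen=int(np.sum(vals == 0.0)),
        median_seen_db=med,
    )


def summarize_exams(exams, grid: Grid) -> pd.DataFrame:
    """Per-exam table of all index values."""
    rows = [index_summary(ex, grid) for ex in exams]
    return pd.DataFrame([r.__dict__ for r in rows])
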