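"""Clustered pointwise endpoints: false-positive probability and change
classification.

A common trial endpoint asks for at least k loci (default 5) changing by at
least delta dB (default 7.0) in the treated eye.  Because each locus has
some probability of exceeding its test-retest repeatability band by chance
alone (5% by the CoR's definition), the chance that k-of-n loci do so is a
binomial tail: with n = 68 loci it is about 25%, falling to about 3% for
the central 36 and 0.1% for the central 16 — the case for restricting
clustered endpoints to central regions.

Global index changes are judged against the index's CoR instead: a change
at or beyond +/-CoR is clinically significant; anything smaller is within
natural test-retest variability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exams import TestPair
from .grid import Grid

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class EndpointSpec:
    """k-of-n pointwise change endpoint."""

    min_loci: int = 5
    delta_db: float = 7.0
    region: str = "all68"  # all68 | central36 | central16
    direction: str = "absolute"  # gain | decline | absolute

    def __post_init__(self) -> None:
        if self.min_loci < 1:
            raise ValueError("min_loci must be >= 1")
        if self.delta_db <= 0:
            raise ValueError("delta_db must be positive")


@dataclass(frozen=True)
class ChangeClassification:
    """Pointwise categorisation of one test pair.

    The flags are not mutually exclusive: a pair can be simultaneously
    gain- and decline-significant.  ``single_label`` collapses to a single
    label with precedence decline > gain > mixed > subthreshold > none.
    """

    patient_id: str
    eye: str
    n_gain: int
    n_decline: int
    gain_significant: bool
    decline_significant: bool
    mixed: bool
    subthreshold: bool
    no_change: bool

    @property
    def single_label(self) -> str:
        if self.decline_significant:
            return "decline"
        if self.gain_significant:
            return "gain"
        if self.mixed:  # implies n_gain + n_decline >= min_loci
            return "mixed"
        if self.subthreshold:
            return "subthreshold"
        return "none"

    @property
    def collapsed(self) -> str:
        """Three-way category for cross-index concordance:
        gain / decline / within."""
        if self.gain_significant and not self.decline_significant:
            return "gain"
        if self.decline_significant and not self.gain_significant:
            return "decline"
        if self.gain_significant and self.decline_significant:
            # a genuinely mixed significant pair matches neither pure label
            return "mixed"
        return "within"


@dataclass(frozen=True)
class GlobalChangeClassification:
    index: str
    delta: float
    cutoff: float
    category: str  # significant_gain | significant_decline | within_variability

    @property
    def collapsed(self) -> str:
        return {"significant_gain": "gain", "significant_decline": "decline",
                "within_variability": "within"}[self.category]


def endpoint_false_positive_prob(n_loci: int, min_loci: int,
                                 per_point_prob: float = 0.05) -> float:
    """P(X >= min_loci) with X ~ Binomial(n_loci, per_point_prob).

    The chance a k-of-n pointwise endpoint is met by per-locus variability
    alone, given each locus independently exceeds its band with the stated
    probability.
    """
    if not 0.0 <= per_point_prob <= 1.0:
        raise ValueError("per_point_prob must be in [0, 1]")
    if not 0 <= min_loci <= n_loci:
        raise ValueError("need 0 <= min_loci <= n_loci")
    if min_loci == 0:
        return 1.0
    return float(stats.binom.sf(min_loci - 1, n_loci, per_point_prob))


def monte_carlo_endpoint_check(n_loci: int, min_loci: int, per_point_prob: float,
                               n_sim: int, seed: int) -> float:
    """Simulation estimate of the endpoint false-positive probability.

    Draws independent per-locus exceedances and reports the fraction of
    simulated exams meeting the k-of-n criterion; converges to the analytic
    binomial tail.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    rng = np.random.default_rng(seed)
    counts = rng.binomial(n_loci, per_point_prob, size=n_sim)
    return float(np.mean(counts >= min_loci))


def classify_pointwise(pair: TestPair, spec: EndpointSpec = EndpointSpec(),
                       grid: Grid | None = None) -> ChangeClassification:
    """Count gain/decline loci of a pair and apply the k-of-n endpoint.

    Differences are raw (non-seen as -1.0 dB), so -1.0 -> 6.0 scores as a
    +7.0 dB gain.  The region subset is applied before counting; regions
    other than all68 require the grid.
    """
    if spec.region == "all68":
        lids = sorted(pair.differences_db)
    else:
        if grid is None:
            raise ValueError("grid required for region subsets")
        lids = grid.region_ids(spec.region)
    d = pair.diff_values(lids)
    n_gain = int(np.sum(d >= spec.delta_db))
    n_decline = int(np.sum(d <= -spec.delta_db))
    k = spec.min_loci
    total = n_gain + n_decline
    return ChangeClassification(
        patient_id=pair.patient_id, eye=pair.eye,
        n_gain=n_gain, n_decline=n_decline,
        gain_significant=n_gain >= k,
        decline_significant=n_decline >= k,
        mixed=(n_gain >= 1 and n_decline >= 1 and total >= k),
        subthreshold=(1 <= total < k),
        no_change=(total == 0),
    )


def classify_global(delta: float, cutoff: float,
                    index: str = "mean_sensitivity") -> GlobalChangeClassification:
    """Judge a global index change (visit2 - visit1) against its CoR.

    The boundary is inclusive: |delta| equal to the cutoff is significant.
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    if delta >= cutoff:
        cat = "significant_gain"
    elif delta <= -cutoff:
        cat = "significant_decline"
    else:
        cat = "within_variability"
    return GlobalChangeClassification(index=index, delta=float(delta),
                                      cutoff=float(cutoff), category=cat)


def concordance(per_pair: Sequence[Mapping[str, str]]) -> dict:
    """Cross-index agreement of per-pair change categories.

    ``per_pair`` holds one mapping per test pair from index name to its
    collapsed category (gain / decline / within / mixed).  Pairs missing
    any index are excluded with a warning.  Returns the agreement count and
    fraction (all indices giving the identical category) plus a
    cross-tabulation DataFrame.
    """
    indices = sorted({k for m in per_pair for k in m})
    rows, excluded = [], 0
    for m in per_pair:
        if set(m) != set(indices):
            excluded += 1
            continue
        rows.append({ix: m[ix] for ix in indices})
    if excluded:
        log.warning("%d pairs missing an index classification: excluded", excluded)
    if not rows:
        return {"n_pairs": 0, "n_agree": 0, "agreement_fraction": float("nan"),
                "table": pd.DataFrame()}
    df = pd.DataFrame(rows)
    agree = df.nunique(axis=1) == 1
    table = df.value_counts().rename("n_pairs").reset_index()
    return {
        "n_pairs": len(df),
        "n_agree": int(agree.sum()),
        "agreement_fraction": float(agree.mean()),
        "table": table,
    }
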