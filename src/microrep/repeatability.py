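"""Repeated-measures Bland-Altman analysis and the coefficient of repeatability.

The coefficient of repeatability (CoR) is 1.96 x the standard deviation of
test-retest differences: the band within which a repeat measurement falls
with 95% probability, and hence the natural-variability threshold a change
must exceed to be called clinically significant.

Pointwise analyses have 68 loci per eye, so differences are clustered
within patients.  The ``mixed`` method models per-locus differences as

    d_il = mu + b_i + e_il,   b_i ~ N(0, s_b^2),  e_il ~ N(0, s_e^2)

with a random intercept b_i per patient i, and uses
sd_diff = sqrt(s_b^2 + s_e^2), so the limits of agreement account for
between-patient clustering.  The ``naive`` method is the classical
Bland-Altman sd of pooled differences, appropriate when each patient
contributes a single value (the global mean- and volume-sensitivity
indices).  Confidence intervals come from a patient-level (cluster)
bootstrap, preserving within-patient correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .exams import TestPair
from .grid import Grid
from .indices import mean_sensitivity, volume_sensitivity

log = logging.getLogger(__name__)

Z_95 = 1.96  # conventional Bland-Altman multiplier


class UndefinedStatisticError(ValueError):
    """Signed-rank statistic undefined (e.g., all paired differences zero)."""


@dataclass(frozen=True)
class PairedSeries:
    """Paired measurements with the clustering unit of each observation."""

    unit_ids: np.ndarray
    values_a: np.ndarray
    values_b: np.ndarray
    level: str = "pointwise"  # "pointwise" | "global"

    def __post_init__(self) -> None:
        if not (len(self.unit_ids) == len(self.values_a) == len(self.values_b)):
            raise ValueError("unit_ids, values_a, values_b must have equal length")

    @property
    def differences(self) -> np.ndarray:
        return np.asarray(self.values_b, float) - np.asarray(self.values_a, float)

    @property
    def n_units(self) -> int:
        return len(np.unique(self.unit_ids))


@dataclass(frozen=True)
class BAResult:
    bias: float
    sd_diff: float
    loa_lower: float
    loa_upper: float
    cor: float
    var_between: float
    var_within: float
    method: str
    level: str
    n_obs: int
    n_units: int
    n_boot: int = 0
    ci_bias: tuple[float, float] | None = None
    ci_loa_lower: tuple[float, float] | None = None
    ci_loa_upper: tuple[float, float] | None = None


@dataclass(frozen=True)
class PairedTestResult:
    statistic: float
    p_raw: float
    p_adjusted: float
    adjustment_method: str
    n: int


def _point_estimates(diffs: np.ndarray, units: np.ndarray, method: str
                     ) -> tuple[float, float, float, float]:
    """(bias, sd_diff, var_between, var_within) for one realisation."""
    if method == "naive":
        bias = float(np.mean(diffs))
        sd = float(np.std(diffs, ddof=1)) if len(diffs) > 1 else 0.0
        return bias, sd, 0.0, sd * sd
    if method != "mixed":
        raise ValueError(f"unknown Bland-Altman method {method!r}")

    uniq = np.unique(units)
    if len(uniq) < 2:
        raise ValueError("mixed method requires >= 2 units (patients)")
    if np.ptp(diffs) == 0.0:
        return float(diffs[0]), 0.0, 0.0, 0.0
    with warnings.catch_warnings():
        # variance components at the boundary (s_b ~ 0) trip harmless
        # convergence warnings; the REML point estimates remain valid
        warnings.simplefilter("ignore")
        model = sm.MixedLM(np.asarray(diffs, float),
                           np.ones((len(diffs), 1)),
                           groups=np.asarray(units))
        fit = model.fit(reml=True, method="powell")
    var_b = float(np.asarray(fit.cov_re)[0, 0])
    var_e = float(fit.scale)
    bias = float(fit.fe_params[0])
    return bias, float(np.sqrt(var_b + var_e)), var_b, var_e


def bland_altman(series: PairedSeries, method: str = "mixed",
                 n_boot: int = 1000, seed: int | None = None,
                 ci_level: float = 0.95) -> BAResult:
    """Bias, limits of agreement and CoR for a paired series.

    ``n_boot`` patient-level bootstrap replicates give percentile
    confidence intervals for the bias and both limits of agreement; pass
    ``n_boot=0`` to skip the bootstrap.  ``seed`` is required when
    ``n_boot > 0`` so results are reproducible.
    """
    diffs = series.differences
    if len(diffs) < 2:
        raise ValueError("need >= 2 paired observations")
    units = np.asarray(series.unit_ids)
    bias, sd, var_b, var_e = _point_estimates(diffs, units, method)
    cor = Z_95 * sd

    ci_bias = ci_lo = ci_hi = None
    if n_boot > 0:
        if seed is None:
            raise ValueError("seed is required when bootstrapping")
        rng = np.random.default_rng(seed)
        uniq = np.unique(units)
        groups = {u: diffs[units == u] for u in uniq}
        stats_boot = np.empty((n_boot, 3))
        for k in range(n_boot):
            chosen = rng.choice(uniq, size=len(uniq), replace=True)
            d = np.concatenate([groups[u] for u in chosen])
            g = np.concatenate([np.full(len(groups[u]), j)
                                for j, u in enumerate(chosen)])
            try:
                b, s, _, _ = _point_estimates(d, g, method)
            except ValueError:  # degenerate resample (single unit)
                b, s = float(np.mean(d)), float(np.std(d, ddof=1))
            stats_boot[k] = (b, b - Z_95 * s, b + Z_95 * s)
        alpha = (1.0 - ci_level) / 2.0
        qs = np.quantile(stats_boot, [alpha, 1.0 - alpha], axis=0)
        ci_bias = (float(qs[0, 0]), float(qs[1, 0]))
        ci_lo = (float(qs[0, 1]), float(qs[1, 1]))
        ci_hi = (float(qs[0, 2]), float(qs[1, 2]))

    return BAResult(
        bias=bias, sd_diff=sd, loa_lower=bias - cor, loa_upper=bias + cor,
        cor=cor, var_between=var_b, var_within=var_e,
        method=method, level=series.level, n_obs=len(diffs),
        n_units=series.n_units, n_boot=n_boot,
        ci_bias=ci_bias, ci_loa_lower=ci_lo, ci_loa_upper=ci_hi,
    )


def pointwise_series(pairs: Sequence[TestPair], grid: Grid,
                     region: str = "all68") -> PairedSeries:
    """Per-locus paired thresholds pooled over pairs, clustered by patient."""
    lids = grid.region_ids(region)
    units, va, vb = [], [], []
    for p in pairs:
        units.extend([p.patient_id] * len(lids))
        va.append(p.exam_a.values(locus_ids=lids))
        vb.append(p.exam_b.values(locus_ids=lids))
    return PairedSeries(np.asarray(units), np.concatenate(va),
                        np.concatenate(vb), level="pointwise")


def global_series(pairs: Sequence[TestPair], index: str, grid: Grid) -> PairedSeries:
    """One index value per exam per pair (unit = patient)."""
    if index == "mean_sensitivity":
        f = lambda ex: mean_sensitivity(ex)
    elif index == "volume_sensitivity":
        f = lambda ex: volume_sensitivity(ex, grid)
    else:
        raise ValueError(f"unknown global index {index!r}")
    units = np.asarray([p.patient_id for p in pairs])
    va = np.asarray([f(p.exam_a) for p in pairs])
    vb = np.asarray([f(p.exam_b) for p in pairs])
    return PairedSeries(units, va, vb, level="global")


def cor_by_eye(pairs: Sequence[TestPair], index: str, grid: Grid,
               n_boot: int = 1000, seed: int | None = None,
               region: str = "all68") -> dict[str, BAResult]:
    """Per-eye Bland-Altman results for one sensitivity index.

    Pointwise series use the mixed (random-intercept) method; the global
    indices contribute one value per patient-eye and use the naive method.
    Eyes are reported right then left.
    """
    out: dict[str, BAResult] = {}
    for i, eye in enumerate(("right", "left")):
        eye_pairs = [p for p in pairs if p.eye == eye]
        if not eye_pairs:
            log.warning("no pairs for %s eye: omitted", eye)
            continue
        eye_seed = None if seed is None else (seed + i)
        if index == "pointwise":
            series = pointwise_series(eye_pairs, grid, region)
            method = "mixed" if series.n_units >= 2 else "naive"
        else:
            series = global_series(eye_pairs, index, grid)
            method = "naive"
        out[eye] = bland_altman(series, method=method, n_boot=n_boot, seed=eye_seed)
    return out


def round_cor_convention(cor: float) -> float:
    """Round a CoR down to the nearest whole dB (the convenience convention
    used when turning a pointwise CoR into a per-point exceedance cutoff)."""
    if cor < 0:
        raise ValueError("CoR must be non-negative")
    floored = float(np.floor(cor))
    if cor < 1.0 and cor > 0.0:
        log.warning("rounding CoR %.3g down to 0: cutoff degenerates", cor)
    return floored


def paired_wilcoxon(values_a, values_b, adjustment: str = "none",
                    n_family: int = 1) -> PairedTestResult:
    """Wilcoxon signed-rank test on paired values.

    Zero differences are dropped (Wilcoxon's original policy).  When the
    test belongs to a family of ``n_family`` simultaneous comparisons, the
    single p-value is Bonferroni-scaled; for full step-down adjustment of a
    family use :func:`adjust_pvalues` on the collected raw p-values.
    """
    a = np.asarray(values_a, float)
    b = np.asarray(values_b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    d = b - a
    if np.all(d == 0):
        raise UndefinedStatisticError("all paired differences are zero")
    res = stats.wilcoxon(b, a, zero_method="wilcox", method="auto")
    n_eff = int(np.sum(d != 0))
    if adjustment == "none" or n_family <= 1:
        p_adj = float(res.pvalue)
    elif adjustment in ("bonferroni", "holm"):
        p_adj = min(1.0, float(res.pvalue) * n_family)
    else:
        raise ValueError(f"unknown adjustment {adjustment!r}")
    return PairedTestResult(statistic=float(res.statistic),
                            p_raw=float(res.pvalue), p_adjusted=p_adj,
                            adjustment_method=adjustment, n=n_eff)


def adjust_pvalues(p_raw: Sequence[float], method: str = "holm") -> np.ndarray:
    """Family-wise adjustment of raw p-values (holm, bonferroni or none)."""
    p = np.asarray(p_raw, float)
    if method == "none":
        return p
    if method not in ("holm", "bonferroni"):
        raise ValueError(f"unknown adjustment {method!r}")
    return multipletests(p, method=method)[1]


def mixed_sensitivity_cor(pairs: Sequence[TestPair], grid: Grid) -> dict:
    """Secondary formulation: model the sensitivity values themselves.

    Fits threshold ~ occasion + C(locus) with a patient random intercept.
    Since a test-retest difference cancels the patient intercept and the
    locus effect, the implied difference sd is sqrt(2) x residual sd; the
    returned ``cor`` is 1.96 x that.  Provided for comparison with the
    primary difference-based model.
    """
    rows = []
    for p in pairs:
        for occ, ex in ((0, p.exam_a), (1, p.exam_b)):
            for lid, t in ex.thresholds_db.items():
                rows.append((p.patient_id, occ, lid, t))
    df = pd.DataFrame(rows, columns=["patient", "occasion", "locus", "threshold"])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = sm.MixedLM.from_formula(
            "threshold ~ occasion + C(locus)", groups="patient", data=df
        ).fit(reml=True, method="powell")
    sigma_e = float(np.sqrt(fit.scale))
    return {
        "occasion_effect": float(fit.fe_params["occasion"]),
        "sigma_patient": float(np.sqrt(np.asarray(fit.cov_re)[0, 0])),
        "sigma_resid": sigma_e,
        "sd_diff": float(np.sqrt(2.0) * sigma_e),
        "cor": float(Z_95 * np.sqrt(2.0) * sigma_e),
    }


def ba_results_frame(results: Mapping[str, BAResult], index: str) -> pd.DataFrame:
    rows = []
    for eye, r in results.items():
        rows.append({
            "index": index, "eye": eye, "method": r.method, "n_obs": r.n_obs,
            "n_units": r.n_units, "bias": r.bias, "sd_diff": r.sd_diff,
            "loa_lower": r.loa_lower, "loa_upper": r.loa_upper, "cor": r.cor,
            "var_between": r.var_between, "var_within": r.var_within,
            "n_boot": r.n_boot,
            "ci_bias_lo": None if r.ci_bias is None else r.ci_bias[0],
            "ci_bias_hi": None if r.ci_bias is None else r.ci_bias[1],
            "ci_loa_lower_lo": None if r.ci_loa_lower is None else r.ci_loa_lower[0],
            "ci_loa_lower_hi": None if r.ci_loa_lower is None else r.ci_loa_lower[1],
            "ci_loa_upper_lo": None if r.ci_loa_upper is None else r.ci_loa_upper[0],
            "ci_loa_upper_hi": None if r.ci_loa_upper is None else r.ci_loa_upper[1],
        })
    return pd.DataFrame(rows)
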