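"""Synthetic RP-like microperimetry cohorts.

Rod-cone dystrophies such as RPGR-associated retinitis pigmentosa show a
preserved central island surrounded by a parafoveal ring scotoma that
widens inward and outward over time.  The latent field model captures that
shape radially:

    latent(x, y) = s_center
                   - ring_depth * exp(-(r - ring_radius)^2 / (2 ring_width^2))
                   - peripheral_slope * max(0, r - ring_radius)
                   - progression_rate * years_elapsed,      r = sqrt(x^2+y^2)

Observation adds a per-exam patient shift (clustering), per-locus Gaussian
noise, optional integer-dB quantization (the staircase's grid), a 36 dB
ceiling, and the device floor: any value below 0 dB is recorded as the
non-seen code -1.0.  The result reproduces the statistical signatures the
analyses assume — positively skewed pointwise distributions with the mode
at -1.0 dB, roughly a third of loci non-seen at mid stage, and a pointwise
test-retest CoR near +/-9 dB under the default noise.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from importlib import resources
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .exams import Exam, MAX_DB, NON_SEEN_DB
from .grid import Grid, build_grid_10_2


@dataclass(frozen=True)
class FieldModel:
    """Latent (noise-free) sensitivity surface of one patient."""

    s_center_db: float = 22.0
    ring_radius_deg: float = 5.0
    ring_width_deg: float = 2.0
    ring_depth_db: float = 26.0
    peripheral_slope_db_per_deg: float = 1.5
    progression_db_per_year: float = 0.8

    def __post_init__(self) -> None:
        if not 0.0 <= self.s_center_db <= MAX_DB:
            raise ValueError("s_center_db outside [0, 36]")
        for name in ("ring_width_deg", "ring_depth_db",
                     "peripheral_slope_db_per_deg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")


@dataclass(frozen=True)
class NoiseModel:
    """Measurement model applied on top of the latent field."""

    sigma_within_db: float = 4.85 / np.sqrt(2)  # per-exam; difference sd 4.85
    sigma_patient_db: float = 0.0
    quantize: bool = True
    fixation_loss_beta: tuple[float, float] = (1.0, 19.0)  # pct / 100 ~ Beta

    def __post_init__(self) -> None:
        if self.sigma_within_db < 0 or self.sigma_patient_db < 0:
            raise ValueError("noise sds must be >= 0")


def true_field(model: FieldModel, grid: Grid, years_elapsed: float = 0.0
               ) -> dict[int, float]:
    """Latent sensitivity at each locus; not yet quantized or censored."""
    xy = grid.coords()
    r = np.hypot(xy[:, 0], xy[:, 1])
    latent = (
        model.s_center_db
        - model.ring_depth_db
        * np.exp(-((r - model.ring_radius_deg) ** 2)
                 / (2.0 * model.ring_width_deg ** 2))
        - model.peripheral_slope_db_per_deg * np.maximum(0.0, r - model.ring_radius_deg)
        - model.progression_db_per_year * years_elapsed
    )
    return dict(zip(grid.locus_ids, latent.astype(float)))


def observe_exam(latent: Mapping[int, float], noise: NoiseModel, seed,
                 patient_id: str = "P00", eye: str = "right",
                 visit: int = 1, test_index: int = 1) -> Exam:
    """One noisy examination of a latent field.

    ``seed`` may be an int or a numpy Generator.  Order of operations:
    noise, quantization, 36 dB ceiling, then floor-censoring to -1.0.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    lids = sorted(latent)
    vals = np.array([latent[lid] for lid in lids], dtype=float)
    vals = vals + rng.normal(0.0, noise.sigma_patient_db) if noise.sigma_patient_db > 0 else vals
    if noise.sigma_within_db > 0:
        vals = vals + rng.normal(0.0, noise.sigma_within_db, size=len(vals))
    if noise.quantize:
        vals = np.round(vals)
    vals = np.minimum(vals, MAX_DB)
    vals = np.where(vals < 0.0, NON_SEEN_DB, vals)
    a, b = noise.fixation_loss_beta
    fl = float(100.0 * rng.beta(a, b))
    return Exam(patient_id=patient_id, eye=eye, visit=visit,
                test_index=test_index,
                thresholds_db=dict(zip(lids, vals.astype(float))),
                fixation_loss_pct=fl)


def load_presets() -> dict:
    """Disease-stage parameter presets (config data shipped with the package)."""
    text = resources.files("microrep").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)


def sample_field_model(preset: str | Mapping, rng: np.random.Generator) -> FieldModel:
    """Draw one patient's FieldModel from a preset's base values + jitter sds."""
    cfg = load_presets()[preset] if isinstance(preset, str) else dict(preset)
    jitter = cfg.get("jitter", {})
    params = {}
    for f in ("s_center_db", "ring_radius_deg", "ring_width_deg", "ring_depth_db",
              "peripheral_slope_db_per_deg", "progression_db_per_year"):
        base = float(cfg[f])
        sd = float(jitter.get(f, 0.0))
        v = base + (rng.normal(0.0, sd) if sd > 0 else 0.0)
        params[f] = v
    params["s_center_db"] = float(np.clip(params["s_center_db"], 0.0, MAX_DB))
    for f in ("ring_width_deg", "ring_depth_db", "peripheral_slope_db_per_deg"):
        params[f] = max(params[f], 1e-6 if f == "ring_width_deg" else 0.0)
    return FieldModel(**params)


def simulate_cohort(
    n_patients: int,
    field_model_dist: str | Mapping | Callable[[np.random.Generator], FieldModel] = "mid",
    noise: NoiseModel = NoiseModel(),
    design: str = "triplicate",
    follow_up_years: float = 1.0,
    seed: int = 0,
    grid: Grid | None = None,
    eyes: Sequence[str] = ("right", "left"),
    inter_eye_offset_sd_db: float = 0.5,
) -> list[Exam]:
    """Simulate a full cohort of examinations.

    ``triplicate``: three same-visit tests per eye from one latent field
    (test 1 is the learning test the pairing step drops).  ``two_visit``:
    one test per eye at visit 1 and at visit 2, the field progressed by
    ``follow_up_years``.  Bit-reproducible from ``seed``.
    """
    if n_patients < 1:
        raise ValueError("n_patients must be >= 1")
    if design not in ("triplicate", "two_visit"):
        raise ValueError(f"unknown design {design!r}")
    grid = grid or build_grid_10_2()
    rng = np.random.default_rng(seed)
    draw = (field_model_dist if callable(field_model_dist)
            else (lambda r: sample_field_model(field_model_dist, r)))

    exams: list[Exam] = []
    for i in range(n_patients):
        pid = f"P{i:03d}"
        model = draw(rng)
        for eye in eyes:
            # both eyes share the field model up to a small offset
            # (progression is highly symmetric between eyes in RPGR-RP)
            offset = rng.normal(0.0, inter_eye_offset_sd_db) if inter_eye_offset_sd_db > 0 else 0.0
            eye_model = replace(model, s_center_db=float(
                np.clip(model.s_center_db + offset, 0.0, MAX_DB)))
            if design == "triplicate":
                latent = true_field(eye_model, grid, 0.0)
                for t in (1, 2, 3):
                    exams.append(observe_exam(latent, noise, rng, pid, eye,
                                              visit=1, test_index=t))
            else:
                for visit, years in ((1, 0.0), (2, follow_up_years)):
                    latent = true_field(eye_model, grid, years)
                    exams.append(observe_exam(latent, noise, rng, pid, eye,
                                              visit=visit, test_index=1))
    return exams
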