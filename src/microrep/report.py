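"""End-to-end pipeline: validate -> pair -> indices -> repeatability ->
endpoints -> classification, with a reproducible run log.

Every cutoff (pointwise delta, cluster size k, global-index cutoffs) is
configuration, never hard-coded: repeatability — and therefore what counts
as a clinically significant change — is population-specific, so cutoffs
must be supplied or derived from the cohort under study.  When a global
cutoff is not supplied it defaults to the larger (more conservative) of
the two per-eye CoRs computed from the same data.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .endpoints import EndpointSpec, classify_global, classify_pointwise, concordance
from .exams import Exam, filter_reliable, load_exams, make_pairs
from .grid import Grid, build_grid_10_2
from .indices import mean_sensitivity, summarize_exams, volume_sensitivity
from .repeatability import ba_results_frame, cor_by_eye
from .synthetic import NoiseModel, simulate_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    out_dir: str
    seed: int | None = None
    # input: either a CSV of exams or a synthetic cohort
    exams_csv: str | None = None
    simulate_patients: int = 0
    simulate_preset: str = "mid"
    simulate_design: str = "triplicate"
    follow_up_years: float = 1.0
    # analysis settings
    area_method: str = "uniform"
    pairing: str = "test2_vs_test3"
    max_fixation_loss_pct: float = 30.0
    n_boot: int = 1000
    delta_db: float = 7.0
    min_loci: int = 5
    region: str = "all68"
    ms_cutoff: float | None = None
    vol_cutoff: float | None = None

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def _write_csv(df: pd.DataFrame, path: Path, cfg_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# microrep {__version__} config_hash={cfg_hash}\n")
        df.to_csv(fh, index=False)


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis and write the report bundle to ``out_dir``.

    Returns a dict with the per-stage results (DataFrames and summaries).
    Any stage failure raises :class:`PipelineError` naming the stage, and
    partial outputs are removed.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cfg_hash = config.config_hash()
    written: list[Path] = []
    stage = "setup"
    try:
        grid = build_grid_10_2(area_method=config.area_method)

        stage = "input"
        if config.exams_csv:
            exams = load_exams(config.exams_csv, grid)
        elif config.simulate_patients > 0:
            if config.seed is None:
                raise ValueError("seed required to simulate a cohort")
            exams = simulate_cohort(
                config.simulate_patients, config.simulate_preset,
                NoiseModel(), design=config.simulate_design,
                follow_up_years=config.follow_up_years, seed=config.seed,
                grid=grid,
            )
        else:
            raise ValueError("no input: set exams_csv or simulate_patients")

        stage = "reliability-filter"
        kept, excluded = filter_reliable(exams, config.max_fixation_loss_pct)

        stage = "pairing"
        pairs = make_pairs(kept, config.pairing)
        if not pairs:
            raise ValueError("no complete test pairs after filtering")

        stage = "indices"
        idx_df = summarize_exams(kept, grid)
        _write_csv(idx_df, out / "indices.csv", cfg_hash)
        written.append(out / "indices.csv")

        stage = "bland-altman"
        if config.n_boot > 0 and config.seed is None:
            raise ValueError("seed required when bootstrapping")
        ba = {
            ix: cor_by_eye(pairs, ix, grid, n_boot=config.n_boot,
                           seed=config.seed, region=config.region)
            for ix in ("pointwise", "mean_sensitivity", "volume_sensitivity")
        }
        ba_df = pd.concat(
            [ba_results_frame(res, ix) for ix, res in ba.items()],
            ignore_index=True,
        )
        _write_csv(ba_df, out / "bland_altman.csv", cfg_hash)
        written.append(out / "bland_altman.csv")

        stage = "classification"
        ms_cut = config.ms_cutoff or max(r.cor for r in ba["mean_sensitivity"].values())
        vol_cut = config.vol_cutoff or max(r.cor for r in ba["volume_sensitivity"].values())
        spec = EndpointSpec(min_loci=config.min_loci, delta_db=config.delta_db,
                            region=config.region)
        rows, cats = [], []
        for p in pairs:
            ptw = classify_pointwise(p, spec, grid)
            ms = classify_global(
                mean_sensitivity(p.exam_b) - mean_sensitivity(p.exam_a),
                ms_cut, "mean_sensitivity")
            vol = classify_global(
                volume_sensitivity(p.exam_b, grid) - volume_sensitivity(p.exam_a, grid),
                vol_cut, "volume_sensitivity")
            rows.append({
                "patient_id": p.patient_id, "eye": p.eye,
                "n_gain": ptw.n_gain, "n_decline": ptw.n_decline,
                "pointwise_label": ptw.single_label,
                "pointwise_category": ptw.collapsed,
                "ms_delta": ms.delta, "ms_category": ms.collapsed,
                "vol_delta": vol.delta, "vol_category": vol.collapsed,
            })
            cats.append({"pointwise": ptw.collapsed, "mean_sensitivity": ms.collapsed,
                         "volume_sensitivity": vol.collapsed})
        cls_df = pd.DataFrame(rows)
        _write_csv(cls_df, out / "classification.csv", cfg_hash)
        written.append(out / "classification.csv")

        stage = "summary"
        conc = concordance(cats)
        summary = pd.DataFrame([
            {"category": cat,
             "pointwise": int((cls_df["pointwise_category"] == cat).sum()),
             "mean_sensitivity": int((cls_df["ms_category"] == cat).sum()),
             "volume_sensitivity": int((cls_df["vol_category"] == cat).sum())}
            for cat in ("gain", "decline", "mixed", "within")
        ])
        _write_csv(summary, out / "summary.csv", cfg_hash)
        written.append(out / "summary.csv")

        run_log = {
            "microrep_version": __version__,
            "config": asdict(config),
            "config_hash": cfg_hash,
            "n_exams": len(exams), "n_excluded": len(excluded),
            "n_pairs": len(pairs),
            "ms_cutoff_used": float(ms_cut), "vol_cutoff_used": float(vol_cut),
            "concordance_fraction": conc["agreement_fraction"],
        }
        (out / "run_log.json").write_text(json.dumps(run_log, indent=2))
        written.append(out / "run_log.json")
    except Exception as exc:
        for p in written:
            p.unlink(missing_ok=True)
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    return {"grid": grid, "exams": exams, "excluded": excluded, "pairs": pairs,
            "indices": idx_df, "bland_altman": ba_df, "ba_results": ba,
            "classification": cls_df, "summary": summary,
            "concordance": conc, "run_log": run_log}
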