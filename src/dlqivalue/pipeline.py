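"""End-to-end orchestration: simulate -> screen -> fit -> select -> value set.

Every stage exchanges data through long-format CSV (one row per valuation), so
any stage can also be run standalone on externally supplied data after column
mapping. Outputs are written to a directory together with a manifest listing
every artifact with a content hash, the configuration, and the seeds used.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import design as design_mod
from .design import DummyDesign, assign_blocks, build_catalogue, generate_orthogonal_core
from .model import TTORandomIntercept, combine_scalable, fit_indices
from .screening import ScreeningConfig, screen_sample
from .selection import backward_eliminate, finalize_model
from .simulate import SimulationParams, SurveyDataset, simulate_cohort
from .valueset import adjust_for_nontraders, average_models, build_value_set

logger = logging.getLogger("dlqivalue")

__all__ = ["PipelineConfig", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration for a full pipeline run (also loadable from YAML)."""

    out_dir: str = "dlqivalue_out"
    input_csv: str | None = None  # if None, a cohort is simulated
    n_respondents: int = 2001
    n_core_states: int = 64
    n_blocks: int = 18
    design_seed: int = 1
    block_seed: int = 2
    sim_seed: int = 3
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    sim_params: SimulationParams | None = None
    n_quad: int = 15
    families_valueset: tuple[str, ...] = ("censored", "scalable_censored")
    families_cv: tuple[str, ...] | None = None  # default: all seven
    w_mode: str = "nontraders_over_initial"  # or nontraders_over_valuers
    run_selection: bool = True

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "screening" in raw:
            raw["screening"] = ScreeningConfig(**raw["screening"])
        if "sim_params" in raw and raw["sim_params"] is not None:
            raw["sim_params"] = SimulationParams(**raw["sim_params"])
        for k in ("families_valueset", "families_cv"):
            if k in raw and raw[k] is not None:
                raw[k] = tuple(raw[k])
        return cls(**raw)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, DummyDesign):
        return o.labels
    raise TypeError(f"not JSON serializable: {type(o)}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis; returns a summary dict and writes all artifacts."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "design"
    try:
        catalogue = build_catalogue(generate_orthogonal_core(
            config.n_core_states, rng_seed=config.design_seed))
        blocks = assign_blocks(catalogue, config.n_blocks, rng_seed=config.block_seed)
        catalogue.to_json(out / "catalogue.json")
        _write_json(out / "blocks.json", [
            {"id": b.block_id, "state_ids": list(b.state_ids)} for b in blocks])

        stage = "data"
        if config.input_csv:
            dataset = SurveyDataset.from_csv(config.input_csv)
        else:
            params = config.sim_params or SimulationParams(rng_seed=config.sim_seed)
            dataset = simulate_cohort(catalogue, blocks, config.n_respondents, params)
            dataset.to_csv(out / "survey.csv", out / "survey_truth.csv")

        stage = "screening"
        outcome, traders = screen_sample(dataset, config.screening)
        _write_json(out / "screening.json",
                    {"accounting": outcome.accounting, "w_candidates": outcome.w_candidates})
        traders.to_csv(out / "traders.csv", index=False)
        w = outcome.w_candidates[config.w_mode]
        logger.info("screening: %s", outcome.accounting)

        stage = "selection"
        design = DummyDesign.full()
        selection_report = {}
        families_cv = config.families_cv or (
            "linear", "censored", "ordinal", "beta",
            "scalable_linear", "scalable_censored", "scalable_beta")
        # stage 1 always runs: the value set requires all-non-positive effects
        design, trace1 = backward_eliminate(
            traders, design, families=config.families_valueset, n_quad=config.n_quad)
        selection_report = {
            "stage1_removed": [f"D{i:02d}_L{l}" for i, l in trace1.removed],
            "final": design.labels,
        }
        if config.run_selection:
            final, trace2, cv_results = finalize_model(
                traders, design, families=families_cv, n_quad=config.n_quad)
            selection_report = {
                "stage1_removed": [f"D{i:02d}_L{l}" for i, l in trace1.removed],
                "stage2_removed": [f"D{i:02d}_L{l}" for i, l in trace2.removed],
                "final": final.labels,
            }
            design = final
            cv_report = {
                fam: {
                    "coef_min": {f"D{i:02d}_L{l}": v for (i, l), v in cv.coef_min.items()},
                    "coef_max": {f"D{i:02d}_L{l}": v for (i, l), v in cv.coef_max.items()},
                    "indices": cv.indices,
                }
                for fam, cv in cv_results.items()
            }
            _write_json(out / "cv_report.json", cv_report)
        _write_json(out / "selection.json", selection_report)

        stage = "fit"
        fits, fit_table = {}, {}
        qcols = [f"q{i}" for i in range(1, 11)]
        X_traders = design_mod.design_matrix(traders[qcols].to_numpy(np.int8), design)
        for fam in families_cv:
            res = TTORandomIntercept.from_dataframe(
                traders, design, family=fam, n_quad=config.n_quad).fit()
            fr = res.as_fit_result()
            if fr.scale == "z":
                fr = combine_scalable(res)
            fits[fam] = fr
            fit_table[fam] = fr.to_dict(units=0.01)  # published-table convention
            fit_table[fam]["indices"] = fit_indices(res.predict_utility(X_traders), traders)
        _write_json(out / "fits.json", fit_table)

        stage = "valueset"
        alpha, incr = average_models([fits[f] for f in config.families_valueset])
        trader_vs = build_value_set(alpha, incr, design,
                                    provenance=f"average of {config.families_valueset}")
        adjusted = adjust_for_nontraders(trader_vs, w)
        vs_frame = trader_vs.to_frame().join(
            adjusted.to_frame(), lsuffix="_trader", rsuffix="_adjusted")
        vs_frame.to_csv(out / "value_set.csv", float_format="%.6f")
        _write_json(out / "value_set.json",
                    {"trader": trader_vs.to_dict(), "adjusted": adjusted.to_dict(), "w": w})

        stage = "enumeration"
        from .valueset import concavity_summary, enumerate_distribution

        enum10 = enumerate_distribution(adjusted, total_score=10)
        conc = concavity_summary(adjusted)
        conc.to_csv(out / "score_profile.csv", index=False)
        _write_json(out / "enumeration.json", {
            "score_10": enum10,
            "score_10_trader": enumerate_distribution(trader_vs, total_score=10),
        })

        stage = "manifest"
        artifacts = sorted(p.name for p in out.iterdir() if p.name != "manifest.json")
        manifest = {
            "config": {k: (asdict(v) if hasattr(v, "__dataclass_fields__") else v)
                       for k, v in asdict(config).items()},
            "files": {name: _sha256(out / name) for name in artifacts},
        }
        _write_json(out / "manifest.json", manifest)
        return {
            "accounting": outcome.accounting,
            "w": w,
            "design": design.labels,
            "value_set_adjusted_intercept": adjusted.intercept,
            "score10": enum10,
            "out_dir": str(out),
        }
    except Exception:
        logger.exception("pipeline failed in stage %r; partial outputs kept in %s", stage, out)
        raise
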