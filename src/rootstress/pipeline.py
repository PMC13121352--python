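"""End-to-end orchestration: configuration, file I/O and the full run.

A run chains the stages the analysis prescribes: derive soil physical
states, fit the Busscher resistance model per structure, attach calculated
resistance, normalise elongation rates, split 70/30 stratified by matric
potential, fit the Gaussian elongation surface on the fit set, evaluate on
the held-out set, and contrast the two structures on a (Qp, S) grid.

Tables travel as CSV (header row required), parameters and reports as
JSON, configuration as YAML. A run-log captures seed, config hash and
library versions so a bundle can be reproduced bit-for-bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from . import busscher as _busscher
from . import gaussian_surface as _surface
from .errors import ConfigError, SchemaError, StageError
from .evaluation import evaluate_predictions, split_fit_validate
from .gaussian_surface import normalize_elongation, relative_elongation
from .soil_state import (
    DEFAULT_GROWTH_DURATION_H,
    DEFAULT_PARTICLE_DENSITY,
    DEFAULT_PROCTOR_MAX_BD,
    Structure,
    derive_states_frame,
)
from .synthetic import SyntheticConfig, generate_experiment

log = logging.getLogger("rootstress")


@dataclasses.dataclass
class PipelineConfig:
    """Settings shared by all stages.

    ``normalization_mode`` is "max" (divide rates by the per-structure
    maximum) or "reference" (divide by ``reference_rate``).
    ``qp_source`` selects the resistance fed to the surface: "calculated"
    (from the fitted Busscher model, the default) or "measured".
    """

    column_map: dict = dataclasses.field(default_factory=dict)
    particle_density: float = DEFAULT_PARTICLE_DENSITY
    proctor_max_bd: float = DEFAULT_PROCTOR_MAX_BD
    growth_duration: float = DEFAULT_GROWTH_DURATION_H
    n_starts: int = 20
    seed: int = 0
    fit_fraction: float = 0.7
    stratify_by: str = "matric_potential"
    normalization_mode: str = "max"
    reference_rate: Optional[float] = None
    qp_source: str = "calculated"
    clamp: bool = False
    grid: tuple = _surface.DEFAULT_GRID
    round_re: int = 2
    round_pct: int = 0

    def __post_init__(self):
        for name in ("particle_density", "proctor_max_bd", "growth_duration"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.normalization_mode not in ("max", "reference"):
            raise ConfigError("normalization_mode must be 'max' or 'reference'")
        if self.normalization_mode == "reference" and not self.reference_rate:
            raise ConfigError("reference mode requires reference_rate")
        if self.qp_source not in ("calculated", "measured"):
            raise ConfigError("qp_source must be 'calculated' or 'measured'")

    def to_yaml(self) -> str:
        d = dataclasses.asdict(self)
        d["grid"] = [list(axis) for axis in d["grid"]]
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        d = yaml.safe_load(text) or {}
        if "grid" in d:
            d["grid"] = tuple(tuple(axis) for axis in d["grid"])
        return cls(**d)

    def content_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if df.empty:
        raise SchemaError([], "input table has no rows")
    return df


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except (StageError, SchemaError):
                raise
            except Exception as exc:  # tag the failing stage for the caller
                raise StageError(name, exc) from exc

        return wrapped

    return deco


@_stage("derive-state")
def _derive(df, config):
    return derive_states_frame(df, config.column_map or None)


@_stage("fit-busscher")
def _fit_busscher_per_structure(states, config):
    params = {}
    for structure, group in states.groupby("structure"):
        if "measured_qp" not in group.columns or group["measured_qp"].isna().all():
            raise SchemaError(["measured_qp"], "Busscher fit needs measured_qp")
        g = group.dropna(subset=["measured_qp"])
        params[Structure.coerce(structure)] = _busscher.fit_busscher(
            g["bulk_density"], g["gravimetric_wc"], g["measured_qp"],
            structure=Structure.coerce(structure), seed=config.seed,
        )
    return params


@_stage("fit-surface")
def _fit_surface_per_structure(obs_frames, config):
    return {
        structure: _surface.fit_gaussian_surface(
            frame, structure=structure, n_starts=config.n_starts, seed=config.seed
        )
        for structure, frame in obs_frames.items()
    }


def run_pipeline(
    config: PipelineConfig,
    input_table: Optional[pd.DataFrame] = None,
    input_csv=None,
    simulate: Optional[SyntheticConfig] = None,
    outdir=None,
) -> dict:
    """Run every stage and return (optionally also write) the result bundle.

    Exactly one of ``input_table``, ``input_csv`` or ``simulate`` supplies
    the sample table. The bundle holds the derived-state table, the
    per-structure Busscher and surface parameters, per-structure evaluation
    reports, the structure-contrast grid and a run-log.
    """
    sources = [x is not None for x in (input_table, input_csv, simulate)]
    if sum(sources) != 1:
        raise ConfigError("provide exactly one of input_table, input_csv, simulate")
    if simulate is not None:
        log.info("simulating experiment (seed=%d)", simulate.seed)
        df = generate_experiment(simulate)
    elif input_csv is not None:
        df = read_samples(input_csv)
    else:
        df = input_table.copy()

    states = _derive(df, config)
    log.info("derived states for %d samples", len(states))

    bp = _fit_busscher_per_structure(states, config)
    for structure, p in bp.items():
        log.info("Busscher %s: a=%.4f b=%.4f c=%.4f rmse=%.3f", structure.value, p.a, p.b, p.c, p.rmse)

    # stress coordinates + relative elongation per structure
    obs_fit, obs_val, evals = {}, {}, {}
    rng_offset = 0
    for structure, group in states.groupby("structure"):
        st = Structure.coerce(structure)
        g = group.copy()
        if config.qp_source == "calculated":
            g["qp"] = _busscher.predict_qp(bp[st], g["bulk_density"], g["gravimetric_wc"])
        else:
            g["qp"] = g["measured_qp"]
        if "rate_cm_d" not in g.columns or g["rate_cm_d"].isna().all():
            raise StageError("normalize", SchemaError(["rate_cm_d"], "no elongation rates available"))
        ref = config.reference_rate if config.normalization_mode == "reference" else None
        g["relative"] = normalize_elongation(g["rate_cm_d"].to_numpy(), reference=ref)
        fit_set, val_set = split_fit_validate(
            g.reset_index(drop=True), config.fit_fraction, config.stratify_by, seed=config.seed + rng_offset
        )
        obs_fit[st], obs_val[st] = fit_set, val_set
        rng_offset += 1

    sp = _fit_surface_per_structure(
        {st: f[["relative", "qp", "saturation_pct"]] for st, f in obs_fit.items()}, config
    )
    for st, val_set in obs_val.items():
        pred = relative_elongation(sp[st], val_set["qp"], val_set["saturation_pct"], clamp=config.clamp)
        evals[st] = evaluate_predictions(val_set["relative"], pred)
        log.info(
            "validation %s: n=%d rmse=%.3f d=%s", st.value, evals[st].n, evals[st].rmse, evals[st].d
        )

    contrast = None
    if Structure.FIELD in sp and Structure.PACKED in sp:
        contrast = _surface.compare_structures(sp[Structure.FIELD], sp[Structure.PACKED], config.grid)

    run_log = {
        "seed": config.seed,
        "config_hash": config.content_hash(),
        "config_yaml": config.to_yaml(),
        "n_samples": int(len(states)),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "rootstress": __import__("rootstress").__version__,
        },
    }
    bundle = {
        "states": states,
        "busscher": bp,
        "surface": sp,
        "evaluation": evals,
        "contrast": contrast,
        "run_log": run_log,
    }
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle["states"].to_csv(outdir / "derived_state.csv", index=False)
    for st, p in bundle["busscher"].items():
        (outdir / f"busscher_{st.value}.json").write_text(p.to_json())
    for st, p in bundle["surface"].items():
        (outdir / f"surface_{st.value}.json").write_text(p.to_json())
    for st, rep in bundle["evaluation"].items():
        (outdir / f"evaluation_{st.value}.json").write_text(rep.to_json())
    if bundle["contrast"] is not None:
        bundle["contrast"].to_csv(outdir / "contrast.csv", index=False)
        meta = {"mean_pct_diff": bundle["contrast"].attrs.get("mean_pct_diff")}
        (outdir / "contrast_summary.json").write_text(json.dumps(meta, indent=2))
    (outdir / "run_log.json").write_text(json.dumps(bundle["run_log"], indent=2))
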