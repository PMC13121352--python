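"""Synthetic root-elongation experiments with known ground truth.

The generator emulates the structure of the glasshouse/laboratory design
the analysis assumes: two soil structural conditions — intact no-tillage
cores ("Field", bulk density drawn from a truncated normal) and re-packed
columns ("Packed", six fixed bulk-density levels) — equilibrated at five
matric potentials, with two seedlings per column grown for 87 h. Water
contents come from a van Genuchten retention curve (the real study
published none, so the curve here is synthetic and config-exposed), true
penetration resistance from a Busscher power law, and true relative
elongation from a 3D Gaussian stress surface; Gaussian noise is added to
measured resistance and to relative elongation (truncated at zero).

Because every response is generated from known parameters, fit-recovery
("closure") experiments can quantify the pipeline's estimation error
without any field data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from .busscher import FIELD_BUSSCHER, PACKED_BUSSCHER, BusscherParams, fit_busscher, predict_qp
from .errors import ConfigError, InvalidInputError
from .evaluation import evaluate_predictions, split_fit_validate
from .gaussian_surface import (
    FIELD_SURFACE,
    PACKED_SURFACE,
    GaussianSurfaceParams,
    fit_gaussian_surface,
    relative_elongation,
)
from .soil_state import (
    DEFAULT_GROWTH_DURATION_H,
    DEFAULT_PARTICLE_DENSITY,
    DEFAULT_SAMPLE_VOLUME_CM3,
    Structure,
)

#: Reference elongation rate (cm d^-1) used to convert relative elongation
#: to absolute rates. Inferred from paired published (relative; absolute)
#: values, which imply a common denominator near 4.83 cm d^-1; not itself a
#: published constant.
DEFAULT_REFERENCE_RATE = 4.83


@dataclass
class RetentionParams:
    """van Genuchten water-retention parameters (synthetic stand-in).

    theta(psi) = theta_r + (theta_s - theta_r) / (1 + (alpha |psi|)^n)^(1 - 1/n).

    Defaults are chosen for a very clayey, well-structured Oxisol whose
    macropores drain early: saturation degree ~= 92% at -10 hPa, ~= 78% at
    -60 hPa, ~= 54% at -5000 hPa for a mid-range bulk density.
    """

    theta_r: float = 0.25
    theta_s: float = 0.65
    alpha: float = 0.10  # hPa^-1
    n_shape: float = 1.25

    def __post_init__(self):
        if not (0 <= self.theta_r < self.theta_s <= 1):
            raise InvalidInputError("need 0 <= theta_r < theta_s <= 1")
        if self.alpha <= 0:
            raise InvalidInputError("alpha must be > 0")
        if self.n_shape <= 1:
            raise InvalidInputError("n_shape must be > 1")


def retention_theta(params: RetentionParams, matric_potential) -> float | np.ndarray:
    """Volumetric water content at a (negative) matric potential, m^3 m^-3."""
    psi = np.asarray(matric_potential, dtype=float)
    if np.any(psi > 0):
        raise InvalidInputError("matric_potential must be <= 0 (hPa, tension)")
    m = 1.0 - 1.0 / params.n_shape
    theta = params.theta_r + (params.theta_s - params.theta_r) / (
        1.0 + (params.alpha * np.abs(psi)) ** params.n_shape
    ) ** m
    return float(theta) if theta.ndim == 0 else theta


@dataclass
class SyntheticConfig:
    """Full description of one synthetic experiment.

    Defaults reproduce the emulated design: 22 Field columns per potential
    (110 total) and 3 Packed columns per bulk-density x potential cell
    (6 levels x 5 potentials x 3 = 90).
    """

    seed: int = 0
    structures: tuple = (Structure.FIELD, Structure.PACKED)
    packed_bd_levels: tuple = (1.02, 1.10, 1.18, 1.26, 1.34, 1.42)
    field_bd_mean: float = 1.18
    field_bd_sd: float = 0.10
    field_bd_bounds: tuple = (1.00, 1.45)
    potentials: tuple = (-10.0, -60.0, -100.0, -1000.0, -5000.0)
    field_reps_per_potential: int = 22
    packed_reps_per_cell: int = 3
    retention: RetentionParams = field(default_factory=RetentionParams)
    retention_offset: dict = field(default_factory=lambda: {Structure.FIELD: 0.0, Structure.PACKED: 0.0})
    truth_busscher: dict = field(
        default_factory=lambda: {Structure.FIELD: FIELD_BUSSCHER, Structure.PACKED: PACKED_BUSSCHER}
    )
    truth_surface: dict = field(
        default_factory=lambda: {Structure.FIELD: FIELD_SURFACE, Structure.PACKED: PACKED_SURFACE}
    )
    noise_re_sd: float = 0.05
    noise_qp_sd: float = 0.10
    reference_rate: float = DEFAULT_REFERENCE_RATE
    particle_density: float = DEFAULT_PARTICLE_DENSITY
    growth_duration: float = DEFAULT_GROWTH_DURATION_H
    sample_volume: float = DEFAULT_SAMPLE_VOLUME_CM3

    def __post_init__(self):
        if self.noise_re_sd < 0 or self.noise_qp_sd < 0:
            raise InvalidInputError("noise standard deviations must be >= 0")
        if self.field_reps_per_potential < 1 or self.packed_reps_per_cell < 1:
            raise InvalidInputError("replicate counts must be >= 1")
        self.structures = tuple(Structure.coerce(s) for s in self.structures)
        for s in self.structures:
            if s not in self.truth_busscher or s not in self.truth_surface:
                raise ConfigError(f"truth parameters missing for structure {s.value}")


def _truncnorm(rng, mean, sd, lo, hi, size):
    """Truncated normal by resampling; sd = 0 degenerates to the mean."""
    if sd == 0:
        return np.full(size, float(np.clip(mean, lo, hi)))
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def generate_experiment(config: SyntheticConfig) -> pd.DataFrame:
    """One synthetic sample table, fully reproducible for a fixed seed.

    Per row: structure, bulk density, matric potential, water contents
    (retention curve with per-row theta_s capped at total porosity so the
    saturation degree stays physical), saturated/dry masses consistent with
    the particle-density porosity, true and noisy penetration resistance,
    true and noisy relative elongation, the implied elongation rate and two
    identical seedling root lengths.
    """
    rng = np.random.default_rng(config.seed)
    pd_ = config.particle_density
    rows = []
    for structure in config.structures:
        if structure is Structure.FIELD:
            n = config.field_reps_per_potential * len(config.potentials)
            bds = _truncnorm(
                rng, config.field_bd_mean, config.field_bd_sd, *config.field_bd_bounds, size=n
            )
            psis = np.repeat(config.potentials, config.field_reps_per_potential)
        else:
            cells = [
                (bd, psi) for psi in config.potentials for bd in config.packed_bd_levels
            ] * config.packed_reps_per_cell
            bds = np.array([c[0] for c in cells])
            psis = np.array([c[1] for c in cells])
            n = len(cells)

        tp = 1.0 - bds / pd_
        offset = config.retention_offset.get(structure, 0.0)
        # cap the retention curve's saturated water content at each row's
        # porosity so S <= 100% by construction
        theta = np.empty(n)
        for i in range(n):
            ret = replace(
                config.retention,
                theta_s=min(config.retention.theta_s, tp[i]) ,
            )
            theta[i] = retention_theta(ret, psis[i]) + offset
        theta = np.clip(theta, 0.0, tp)
        w = theta / bds
        s_pct = 100.0 * theta / tp

        qp_true = predict_qp(config.truth_busscher[structure], bds, w)
        qp_meas = qp_true + rng.normal(0.0, config.noise_qp_sd, size=n)
        qp_meas = np.clip(qp_meas, 1e-3, None)

        re_true = relative_elongation(config.truth_surface[structure], qp_true, s_pct)
        re_obs = np.clip(re_true + rng.normal(0.0, config.noise_re_sd, size=n), 0.0, None)
        rate = re_obs * config.reference_rate
        root_len = rate * config.growth_duration / 24.0

        dry_mass = bds * config.sample_volume  # g, density in Mg m^-3 == g cm^-3
        sat_mass = dry_mass + tp * config.sample_volume

        for i in range(n):
            rows.append(
                {
                    "sample_id": f"{structure.value[0]}{len(rows) + 1:04d}",
                    "structure": structure.value,
                    "bulk_density": bds[i],
                    "gravimetric_wc": w[i],
                    "matric_potential": psis[i],
                    "saturated_mass": sat_mass[i],
                    "dry_mass": dry_mass[i],
                    "sample_volume": config.sample_volume,
                    "measured_qp": qp_meas[i],
                    "qp_calc": qp_true[i],
                    "saturation_pct": s_pct[i],
                    "relative": re_obs[i],
                    "rate_cm_d": rate[i],
                    "root_length_1": root_len[i],
                    "root_length_2": root_len[i],
                    "growth_duration": config.growth_duration,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RecoveryReport:
    """Aggregated results of repeated generate -> split -> fit -> evaluate runs."""

    per_rep: pd.DataFrame
    n_reps: int

    def summary(self) -> pd.DataFrame:
        """Mean per structure of every numeric per-rep column."""
        return self.per_rep.groupby("structure").mean(numeric_only=True)


def _fit_one_structure(df_s, structure, config, seed):
    """Split, fit Busscher + surface on the fit set, evaluate on validation."""
    fit_set, val_set = split_fit_validate(
        df_s.reset_index(drop=True), 0.7, stratify_by="matric_potential", seed=seed
    )
    bp = fit_busscher(
        fit_set["bulk_density"], fit_set["gravimetric_wc"], fit_set["measured_qp"],
        structure=structure, seed=seed,
    )
    for part in (fit_set, val_set):
        part["qp"] = predict_qp(bp, part["bulk_density"], part["gravimetric_wc"])
    sp = fit_gaussian_surface(
        fit_set[["relative", "qp", "saturation_pct"]], structure=structure, seed=seed
    )
    pred = relative_elongation(sp, val_set["qp"], val_set["saturation_pct"])
    report = evaluate_predictions(val_set["relative"], pred)

    truth = config.truth_surface[structure]
    re_fit_hull = relative_elongation(sp, df_s["qp_calc"], df_s["saturation_pct"])
    re_true_hull = relative_elongation(truth, df_s["qp_calc"], df_s["saturation_pct"])
    return bp, sp, report, float(np.max(np.abs(re_fit_hull - re_true_hull)))


def recovery_experiment(config: SyntheticConfig, n_reps: int = 1) -> RecoveryReport:
    """Parameter- and surface-recovery study against the generator's truth.

    For each replicate: generate a fresh table (seed derived from the
    config seed and the replicate index), split 70/30 stratified by matric
    potential within structure, fit the Busscher model on measured
    resistance, recompute calculated resistance from that fit, fit the
    elongation surface, and evaluate on the held-out 30%. Reports, per
    structure and replicate, parameter estimates with errors vs truth,
    validation metrics and the maximum surface deviation from truth over
    the replicate's own (Qp, S) cloud.
    """
    if n_reps < 1:
        raise InvalidInputError("n_reps must be >= 1")
    rows = []
    for rep in range(n_reps):
        rep_seed = int(np.random.SeedSequence([config.seed, rep]).generate_state(1)[0] % (2**31))
        cfg = replace(config, seed=rep_seed)
        table = generate_experiment(cfg)
        for structure in cfg.structures:
            df_s = table[table["structure"] == structure.value]
            bp, sp, report, max_dev = _fit_one_structure(df_s, structure, cfg, rep_seed)
            tb, ts = cfg.truth_busscher[structure], cfg.truth_surface[structure]
            rows.append(
                {
                    "rep": rep,
                    "structure": structure.value,
                    "a_hat": bp.a, "b_hat": bp.b, "c_hat": bp.c,
                    "a_err": bp.a - tb.a, "b_err": bp.b - tb.b, "c_err": bp.c - tb.c,
                    "se_a": bp.se_a, "se_b": bp.se_b, "se_c": bp.se_c,
                    "x0_hat": sp.x0, "y0_hat": sp.y0,
                    "x0_err": sp.x0 - ts.x0, "y0_err": sp.y0 - ts.y0,
                    "se_x0": sp.se_x0, "se_y0": sp.se_y0,
                    "val_rmse": report.rmse, "val_crm": report.crm,
                    "val_r": report.r, "val_d": report.d, "val_n": report.n,
                    "surface_max_dev": max_dev,
                }
            )
    return RecoveryReport(per_rep=pd.DataFrame(rows), n_reps=n_reps)
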