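"""Derived soil physical quantities for root-growth experiments.

Each soil column carries a handful of raw measurements — dry and saturated
masses, gravimetric water content, bulk density, matric potential — from
which the stress variables of the elongation model are derived: total
porosity, volumetric water content, air-filled porosity, degree of water
saturation (S, the hydric-stress variable) and degree of compactness
(bulk density relative to the Proctor-test maximum).

Unit conventions: bulk and particle density in Mg m^-3, gravimetric water
content in kg kg^-1, matric potential in hPa (negative under tension),
porosities and volumetric water content in m^3 m^-3, S and DC in percent.
Water density is fixed at 1.0 g cm^-3 (= 1.0 Mg m^-3) for every
mass-to-volume conversion.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .errors import InvalidInputError, SchemaError

#: Solid-phase density of the very clayey Oxisol, Mg m^-3 (0-0.30 m layer).
DEFAULT_PARTICLE_DENSITY = 2.96
#: Proctor-test maximum bulk density, Mg m^-3.
DEFAULT_PROCTOR_MAX_BD = 1.53
#: Root growth duration in the growth chamber, hours.
DEFAULT_GROWTH_DURATION_H = 87.0
#: PVC cylinder volume, cm^3.
DEFAULT_SAMPLE_VOLUME_CM3 = 298.6
#: Tolerance (m^3 m^-3) by which theta_v may exceed total porosity before a
#: record is rejected rather than merely flagged; absorbs measurement noise.
DEFAULT_POROSITY_TOLERANCE = 0.02


class Structure(str, Enum):
    """Soil structural condition: intact no-tillage cores vs re-packed columns."""

    FIELD = "Field"
    PACKED = "Packed"

    @classmethod
    def coerce(cls, value) -> "Structure":
        if isinstance(value, cls):
            return value
        try:
            return cls(str(value).strip().capitalize())
        except ValueError:
            raise InvalidInputError(
                f"unknown structure {value!r}; expected 'Field' or 'Packed'"
            ) from None


@dataclass
class SampleRecord:
    """One soil column with its raw measurements.

    ``root_length_per_seedling`` holds up to two primary-root lengths (cm),
    one per seedling sub-replicate; the per-sample elongation rate is their
    mean over ``growth_duration`` hours.
    """

    sample_id: str
    structure: Structure
    bulk_density: float
    gravimetric_wc: float
    matric_potential: float
    particle_density: float = DEFAULT_PARTICLE_DENSITY
    proctor_max_bd: float = DEFAULT_PROCTOR_MAX_BD
    measured_qp: Optional[float] = None
    root_length_per_seedling: Sequence[float] = field(default_factory=list)
    growth_duration: float = DEFAULT_GROWTH_DURATION_H
    saturated_mass: Optional[float] = None
    dry_mass: Optional[float] = None
    sample_volume: float = DEFAULT_SAMPLE_VOLUME_CM3

    def __post_init__(self):
        self.structure = Structure.coerce(self.structure)
        if not (0 < self.bulk_density < self.particle_density):
            raise InvalidInputError(
                f"bulk_density {self.bulk_density} must be in (0, particle_density="
                f"{self.particle_density})"
            )
        if self.gravimetric_wc < 0:
            raise InvalidInputError("gravimetric_wc must be >= 0")
        if self.matric_potential >= 0:
            raise InvalidInputError("matric_potential must be negative (hPa, tension)")
        if self.growth_duration <= 0:
            raise InvalidInputError("growth_duration must be > 0")


@dataclass
class SoilPhysicalState:
    """Derived physical state of one sample.

    ``porosity_route`` records whether total porosity came from the
    saturation-mass measurement ("mass") or from 1 - BD/PD ("particle").
    ``oversaturated`` flags theta_v > total porosity (S > 100%), tolerated
    up to the configured tolerance as measurement noise.
    """

    sample_id: str
    total_porosity: float
    theta_v: float
    air_porosity: float
    saturation_pct: float
    compactness_pct: float
    porosity_route: str = "particle"
    oversaturated: bool = False


def total_porosity(saturated_mass: float, dry_mass: float, volume: float) -> float:
    """Total porosity from the saturation-mass route.

    The pore volume equals the mass of water held at saturation (water
    density 1 g cm^-3): (saturated - dry) / volume.

    Parameters are in g, g, cm^3; the result is m^3 m^-3.
    """
    if dry_mass <= 0 or volume <= 0:
        raise InvalidInputError("dry_mass and volume must be positive")
    if saturated_mass < dry_mass:
        raise InvalidInputError("saturated_mass must be >= dry_mass")
    tp = (saturated_mass - dry_mass) / volume
    if tp >= 1:
        raise InvalidInputError(f"total porosity {tp:.3f} >= 1 is unphysical")
    return tp


def total_porosity_from_densities(bulk_density: float, particle_density: float) -> float:
    """Total porosity via the particle-density route, 1 - BD/PD.

    Fallback when saturated/dry masses are not recorded.
    """
    if bulk_density <= 0 or particle_density <= 0:
        raise InvalidInputError("densities must be positive")
    if bulk_density >= particle_density:
        raise InvalidInputError("bulk_density must be < particle_density")
    return 1.0 - bulk_density / particle_density


def volumetric_water_content(gravimetric_wc: float, bulk_density: float) -> float:
    """theta_v = w * BD (water density 1 Mg m^-3)."""
    if gravimetric_wc < 0 or bulk_density < 0:
        raise InvalidInputError("inputs must be non-negative")
    return gravimetric_wc * bulk_density


def degree_of_saturation(theta_v: float, total_porosity: float) -> float:
    """Degree of water saturation S (%) = 100 * theta_v / total porosity.

    Values above 100% are returned as-is (the caller flags them); they arise
    from measurement noise in real tables.
    """
    if total_porosity <= 0:
        raise InvalidInputError("total_porosity must be > 0")
    if theta_v < 0:
        raise InvalidInputError("theta_v must be >= 0")
    return 100.0 * theta_v / total_porosity


def degree_of_compactness(bulk_density: float, proctor_max_bd: float = DEFAULT_PROCTOR_MAX_BD) -> float:
    """Degree of compactness DC (%) = 100 * BD / Proctor maximum BD."""
    if proctor_max_bd <= 0 or bulk_density <= 0:
        raise InvalidInputError("bulk_density and proctor_max_bd must be > 0")
    return 100.0 * bulk_density / proctor_max_bd


def elongation_rate(root_length, duration: float = DEFAULT_GROWTH_DURATION_H) -> float:
    """Root elongation rate in cm d^-1.

    ``root_length`` is a single primary-root length (cm) or a list of up to
    two seedling lengths, averaged before dividing by the duration in days.
    """
    if duration <= 0:
        raise InvalidInputError("duration must be > 0")
    lengths = np.atleast_1d(np.asarray(root_length, dtype=float))
    if lengths.size == 0:
        raise InvalidInputError("at least one root length is required")
    if np.any(lengths < 0):
        raise InvalidInputError("root lengths must be >= 0")
    return float(lengths.mean() / (duration / 24.0))


def derive_state(
    record: SampleRecord,
    porosity_tolerance: float = DEFAULT_POROSITY_TOLERANCE,
) -> SoilPhysicalState:
    """Compute the full derived state of one sample.

    Uses the saturation-mass porosity route when both masses are present,
    the particle-density route otherwise. theta_v exceeding total porosity
    by more than ``porosity_tolerance`` raises; a smaller excess is flagged.
    """
    if record.saturated_mass is not None and record.dry_mass is not None:
        tp = total_porosity(record.saturated_mass, record.dry_mass, record.sample_volume)
        route = "mass"
    else:
        tp = total_porosity_from_densities(record.bulk_density, record.particle_density)
        route = "particle"
    theta = volumetric_water_content(record.gravimetric_wc, record.bulk_density)
    if theta > tp + porosity_tolerance:
        raise InvalidInputError(
            f"theta_v {theta:.3f} exceeds total porosity {tp:.3f} by more than "
            f"the tolerance {porosity_tolerance}"
        )
    s = degree_of_saturation(theta, tp)
    return SoilPhysicalState(
        sample_id=record.sample_id,
        total_porosity=tp,
        theta_v=theta,
        air_porosity=tp - theta,
        saturation_pct=s,
        compactness_pct=degree_of_compactness(record.bulk_density, record.proctor_max_bd),
        porosity_route=route,
        oversaturated=theta > tp,
    )


#: Canonical column names of the sample table; the pipeline config can remap.
REQUIRED_COLUMNS = ("sample_id", "structure", "bulk_density", "gravimetric_wc", "matric_potential")
OPTIONAL_COLUMNS = (
    "measured_qp",
    "saturated_mass",
    "dry_mass",
    "sample_volume",
    "root_length_1",
    "root_length_2",
    "growth_duration",
    "particle_density",
    "proctor_max_bd",
)


def records_from_frame(df: pd.DataFrame, column_map: Optional[dict] = None) -> list[SampleRecord]:
    """Build SampleRecords from a sample table.

    ``column_map`` maps canonical names to the caller's column names.
    Missing required columns raise SchemaError listing them all.
    """
    cmap = {name: name for name in REQUIRED_COLUMNS + OPTIONAL_COLUMNS}
    if column_map:
        cmap.update(column_map)
    missing = [cmap[c] for c in REQUIRED_COLUMNS if cmap[c] not in df.columns]
    if missing:
        raise SchemaError(missing)

    def _get(row, canonical, default=None):
        col = cmap[canonical]
        if col in df.columns and not pd.isna(row[col]):
            return row[col]
        return default

    records = []
    for _, row in df.iterrows():
        lengths = [v for v in (_get(row, "root_length_1"), _get(row, "root_length_2")) if v is not None]
        records.append(
            SampleRecord(
                sample_id=str(row[cmap["sample_id"]]),
                structure=Structure.coerce(row[cmap["structure"]]),
                bulk_density=float(row[cmap["bulk_density"]]),
                gravimetric_wc=float(row[cmap["gravimetric_wc"]]),
                matric_potential=float(row[cmap["matric_potential"]]),
                particle_density=float(_get(row, "particle_density", DEFAULT_PARTICLE_DENSITY)),
                proctor_max_bd=float(_get(row, "proctor_max_bd", DEFAULT_PROCTOR_MAX_BD)),
                measured_qp=(lambda v: None if v is None else float(v))(_get(row, "measured_qp")),
                root_length_per_seedling=[float(v) for v in lengths],
                growth_duration=float(_get(row, "growth_duration", DEFAULT_GROWTH_DURATION_H)),
                saturated_mass=(lambda v: None if v is None else float(v))(_get(row, "saturated_mass")),
                dry_mass=(lambda v: None if v is None else float(v))(_get(row, "dry_mass")),
                sample_volume=float(_get(row, "sample_volume", DEFAULT_SAMPLE_VOLUME_CM3)),
            )
        )
    return records


def derive_states_frame(
    df: pd.DataFrame,
    column_map: Optional[dict] = None,
    porosity_tolerance: float = DEFAULT_POROSITY_TOLERANCE,
) -> pd.DataFrame:
    """Derived-state table (one row per sample) joined to sample_id.

    Adds the elongation rate in cm d^-1 when root lengths are present.
    """
    records = records_from_frame(df, column_map)
    rows = []
    for rec in records:
        st = derive_state(rec, porosity_tolerance)
        row = {
            "sample_id": st.sample_id,
            "structure": rec.structure.value,
            "matric_potential": rec.matric_potential,
            "bulk_density": rec.bulk_density,
            "gravimetric_wc": rec.gravimetric_wc,
            "total_porosity": st.total_porosity,
            "theta_v": st.theta_v,
            "air_porosity": st.air_porosity,
            "saturation_pct": st.saturation_pct,
            "compactness_pct": st.compactness_pct,
            "porosity_route": st.porosity_route,
            "oversaturated": st.oversaturated,
        }
        if rec.measured_qp is not None:
            row["measured_qp"] = rec.measured_qp
        if len(rec.root_length_per_seedling) > 0:
            row["rate_cm_d"] = elongation_rate(rec.root_length_per_seedling, rec.growth_duration)
        rows.append(row)
    return pd.DataFrame(rows)
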