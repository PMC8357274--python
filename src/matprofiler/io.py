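"""Shared I/O: TSV dialects, scenario files and run configuration.

All tabular files are UTF-8, tab-separated, with a header row and '.' as
the decimal mark.  One canonical unit per column is enforced at this
boundary (mm, mol m^-3, nm, kBq, s); unit conversions happen only inside
the physics operations.  Write-then-read round trips reproduce values to
full float precision.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .community import GuildMap, LayerCommunity
from .profiles import DepthProfile, FluxProfile, RateDepthProfile
from .spectra import AttenuationStack, SpectralStack
from .srr import SRRResult, TracerSample
from .synthetic import MatScenario, PigmentBand

_FLOAT_FMT = "%.17g"

#: canonical unit per profile quantity, enforced on read
_EXPECTED_UNITS = {"O2": "mol m-3", "H2S": "mol m-3", "Stot": "mol m-3", "pH": "-"}


def _require_columns(df: pd.DataFrame, required: list[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: malformed header, missing column(s) {missing}")


def write_profile_tsv(profile: DepthProfile, path) -> None:
    df = pd.DataFrame(
        {
            "depth_mm": profile.depth_mm,
            "value": profile.value,
            "unit": profile.unit,
            "quantity": profile.quantity,
            "condition": profile.condition if profile.condition is not None else "",
            "replicate": profile.replicate_id if profile.replicate_id is not None else "",
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_profile_tsv(path) -> DepthProfile:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", dtype={"condition": str, "replicate": str})
    _require_columns(df, ["depth_mm", "value", "unit", "quantity"], path)
    quantity = str(df["quantity"].iloc[0])
    unit = str(df["unit"].iloc[0])
    expected = _EXPECTED_UNITS.get(quantity)
    if expected is not None and unit != expected:
        raise ValueError(
            f"{path}: unit mismatch for {quantity!r}: expected {expected!r}, got {unit!r}"
        )
    condition = df["condition"].iloc[0] if "condition" in df.columns else None
    if condition is not None and (pd.isna(condition) or condition == ""):
        condition = None
    replicate = df["replicate"].iloc[0] if "replicate" in df.columns else None
    if replicate is not None and (pd.isna(replicate) or replicate == ""):
        replicate = None
    return DepthProfile(
        depth_mm=df["depth_mm"].to_numpy(float),
        value=df["value"].to_numpy(float),
        quantity=quantity,
        unit=unit,
        condition=condition,
        replicate_id=replicate,
        validate=False,
    )


def write_spectral_stack(stack: SpectralStack, path) -> None:
    """Wide matrix: first column wavelength_nm, remaining columns depths in mm."""
    df = pd.DataFrame(stack.irradiance, columns=[f"{d:g}" for d in stack.depth_mm])
    df.insert(0, "wavelength_nm", stack.wavelength_nm)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# normalized={str(stack.normalized).lower()}\n")
        df.to_csv(fh, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_spectral_stack(path) -> SpectralStack:
    normalized = False
    with open(path, encoding="utf-8") as fh:
        pos = fh.tell()
        first = fh.readline()
        if first.startswith("#"):
            normalized = "normalized=true" in first.replace(" ", "")
        else:
            fh.seek(pos)
        df = pd.read_csv(fh, sep="\t", float_precision="round_trip")
    _require_columns(df, ["wavelength_nm"], path)
    depth_cols = [c for c in df.columns if c != "wavelength_nm"]
    return SpectralStack(
        wavelength_nm=df["wavelength_nm"].to_numpy(float),
        depth_mm=np.array([float(c) for c in depth_cols]),
        irradiance=df[depth_cols].to_numpy(float),
        normalized=normalized,
    )


def write_attenuation_stack(att: AttenuationStack, path) -> None:
    df = pd.DataFrame(att.attenuation, columns=[f"{d:g}" for d in att.depth_mm])
    df.insert(0, "wavelength_nm", att.wavelength_nm)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


_TRACER_COLUMNS = [
    "core_id",
    "section_top_mm",
    "section_bottom_mm",
    "section_volume_ml",
    "tris_activity_kbq",
    "residual_sulfate_activity_kbq",
    "sulfate_mol_m3",
    "porosity",
    "incubation_time_s",
    "is_blank",
]


def write_tracer_samples(samples: list[TracerSample], path) -> None:
    df = pd.DataFrame([asdict(s) for s in samples])[_TRACER_COLUMNS]
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_tracer_samples(path) -> list[TracerSample]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, _TRACER_COLUMNS, path)
    return [
        TracerSample(
            core_id=str(row.core_id),
            section_top_mm=float(row.section_top_mm),
            section_bottom_mm=float(row.section_bottom_mm),
            section_volume_ml=float(row.section_volume_ml),
            tris_activity_kbq=float(row.tris_activity_kbq),
            residual_sulfate_activity_kbq=float(row.residual_sulfate_activity_kbq),
            sulfate_mol_m3=float(row.sulfate_mol_m3),
            porosity=float(row.porosity),
            incubation_time_s=float(row.incubation_time_s),
            is_blank=bool(row.is_blank),
        )
        for row in df.itertuples()
    ]


def write_srr_results(results: list[SRRResult], path) -> None:
    df = pd.DataFrame(
        {
            "core_id": [r.core_id for r in results],
            "section_top_mm": [r.section_top_mm for r in results],
            "section_bottom_mm": [r.section_bottom_mm for r in results],
            "depth_mid_mm": [r.depth_mid_mm for r in results],
            "rate_mol_m3_s": [r.rate for r in results],
            "below_mdl": [r.below_mdl for r in results],
        }
    )
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_flux_tsv(flux: FluxProfile, path) -> None:
    pd.DataFrame(
        {"depth_mm": flux.depth_mm, "flux_mol_m2_s": flux.flux, "quantity": flux.quantity}
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_rates_tsv(rates: RateDepthProfile, path) -> None:
    pd.DataFrame(
        {"depth_mm": rates.depth_mm, "rate_mol_m3_s": rates.rate, "quantity": rates.quantity}
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def write_rate_table(table: Mapping[str, Mapping[str, float]], path) -> None:
    """Process x column rate table (areal + volumetric per condition)."""
    df = pd.DataFrame.from_dict(table, orient="index")
    df.index.name = "process"
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


# -- community tables ---------------------------------------------------------


def write_abundance_table(rel: pd.DataFrame, path) -> None:
    """Rows taxa, columns layer samples named ``<patch>_<layerIndex>``."""
    out = rel.copy()
    out.index.name = "taxon"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def read_abundance_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip", index_col=0)
    return df.astype(float)


def write_cell_counts(counts: Mapping[str, float], path) -> None:
    pd.DataFrame(
        {"layer": list(counts.keys()), "cells_per_g": list(counts.values())}
    ).to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_cell_counts(path) -> dict[str, float]:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["layer", "cells_per_g"], path)
    return dict(zip(df["layer"].astype(str), df["cells_per_g"].astype(float)))


def write_guild_map(guilds: GuildMap, path) -> None:
    pd.DataFrame(
        {"taxon": list(guilds.mapping.keys()), "guild": list(guilds.mapping.values())}
    ).to_csv(path, sep="\t", index=False)


def read_guild_map(path) -> GuildMap:
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    _require_columns(df, ["taxon", "guild"], path)
    return GuildMap(dict(zip(df["taxon"].astype(str), df["guild"].astype(str))))


def layer_communities_from_tables(
    rel: pd.DataFrame,
    counts_per_layer: Mapping[str, float],
    layer_order: Mapping[str, int] | None = None,
) -> list[LayerCommunity]:
    """Build LayerCommunity objects from an abundance table and cell counts.

    Columns named ``<patch>_<layerIndex>`` are mapped through
    ``layer_order`` (label -> index); plain layer-label columns are treated
    as single unreplicated samples.
    """
    from .community import LAYER_ORDER

    index_to_label = {i: l for i, l in enumerate(LAYER_ORDER)}
    out = []
    for col in rel.columns:
        if "_" in col and col.rsplit("_", 1)[1].isdigit():
            patch, idx = col.rsplit("_", 1)
            layer_index = int(idx)
            label = index_to_label.get(layer_index, col)
        else:
            patch, label = "I", col
            layer_index = LAYER_ORDER.index(label) if label in LAYER_ORDER else 0
        out.append(
            LayerCommunity(
                patch_id=patch,
                layer=label,
                layer_index=layer_index,
                taxon_abundances=dict(rel[col]),
                total_cells_per_g=float(counts_per_layer[label]),
            )
        )
    return out


# -- scenario files -----------------------------------------------------------


def scenario_to_yaml(scenario: MatScenario, path) -> None:
    data = {
        "layer_boundaries_mm": [float(b) for b in scenario.layer_boundaries_mm],
        "true_rates": {k: [float(r) for r in v] for k, v in scenario.true_rates.items()},
        "diffusivity": {k: float(v) for k, v in scenario.diffusivity.items()},
        "boundary_conditions": {
            k: [v if isinstance(v, str) else float(v) for v in pair]
            for k, pair in scenario.boundary_conditions.items()
        },
        "porosity": float(scenario.porosity),
        "correction": scenario.correction,
        "pigment_bands": [asdict(b) for b in scenario.pigment_bands],
        "matrix_attenuation_per_mm": [float(a) for a in scenario.matrix_attenuation_per_mm],
        "salt_thickness_mm": float(scenario.salt_thickness_mm),
        "salt_attenuation_per_mm": float(scenario.salt_attenuation_per_mm),
        "noise_sd": {k: float(v) for k, v in scenario.noise_sd.items()},
        "seed": int(scenario.seed),
    }
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(data, fh, sort_keys=False)


def scenario_from_yaml(path) -> MatScenario:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    bands = tuple(PigmentBand(**b) for b in data.pop("pigment_bands", []))
    bcs = {
        k: tuple(v if isinstance(v, str) else float(v) for v in pair)
        for k, pair in data.pop("boundary_conditions", {}).items()
    }
    return MatScenario(pigment_bands=bands, boundary_conditions=bcs, **data)


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    scenario_path: str | None = None  # None: the bundled default scenario
    out_dir: str = "matprofiler_out"
    seed: int = 0
    grid_step_mm: float = 0.05
    oxic_threshold_mol_m3: float = 0.0
    mat_bottom_mm: float | None = None  # default: the scenario's bottom boundary
    srr_horizon_mm: float = 30.0
    n_tracer_replicates: int = 3
    n_blanks: int = 4
    log_level: str = "INFO"
    extra: dict = field(default_factory=dict)

    def validate(self) -> None:
        if self.scenario_path is not None and not Path(self.scenario_path).exists():
            raise FileNotFoundError(f"scenario file not found: {self.scenario_path}")
        if self.grid_step_mm <= 0:
            raise ValueError("grid_step_mm must be > 0")


def run_config_from_yaml(path) -> RunConfig:
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh) or {}
    known = {f for f in RunConfig.__dataclass_fields__}
    kwargs = {k: v for k, v in data.items() if k in known}
    kwargs["extra"] = {k: v for k, v in data.items() if k not in known}
    cfg = RunConfig(**kwargs)
    cfg.validate()
    return cfg
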