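"""File formats, packaged fixtures, configuration and the full pipeline.

All tabular interchange is UTF-8 CSV with explicit headers, decimal
points, and units embedded in column names. Floats are written with
Python's shortest round-trip representation, so a write/read cycle is
lossless well beyond 12 significant digits.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Any, Mapping, Sequence

import pandas as pd
import yaml

from .biomass import (
    BiomeParams,
    CANONICAL_BIOMES,
    DEFAULT_DIET_FRACTIONS,
    DEFAULT_INSECTIVORE_FRACTIONS,
    DEFAULT_NONBREEDING_MULTIPLIER,
    TROPICAL_BIOMES,
    biome_standing_biomass,
    global_standing_biomass,
    insectivore_standing_biomass,
    round_half_up,
)
from .consumption import (
    AdjustmentFlags,
    BiomeSummary,
    ConsumptionRecord,
    GLOBAL_TERRESTRIAL_NPP_J,
    GlobalEstimate,
    biome_group_shares,
    global_total,
    gross_energy_and_npp_fraction,
    harmonize_record,
    scenario_bounds,
    stopover_consumption,
    summarize_biome,
)
from .energetics import DEFAULT_CONSTANTS, EcophysConstants
from .rank_stats import GroupedSamples, consumption_npp_correlation, dunn_test

__all__ = [
    "RunConfig",
    "fixture_path",
    "read_biome_table",
    "read_summary_table",
    "read_npp_reference",
    "read_records_csv",
    "write_records_csv",
    "load_esm1_transcription",
    "TranscriptionPending",
    "run_full_pipeline",
    "stats_from_records",
    "constants_from_config",
]

_FIXTURES = {
    "table1": "table1_biomass.csv",
    "table2": "table2_consumption.csv",
    "npp": "npp_reference.csv",
    "table3": "table3_reference.csv",
    "esm1_template": "esm1_transcription_template.csv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged fixture (table1, table2, npp, ...)."""
    if name not in _FIXTURES:
        raise ValueError(f"unknown fixture {name!r}; choose from {sorted(_FIXTURES)}")
    return Path(str(resources.files("aviprey").joinpath("data", _FIXTURES[name])))


def read_biome_table(path: str | Path | None = None) -> list[BiomeParams]:
    """Read a biome parameter table (packaged canonical table by default).

    Expected columns: biome, density_per_ha, mass_kg, area_ha,
    climate_class. Insectivore/diet fractions and the non-breeding
    multiplier are attached from the canonical defaults. A proper
    subset of the seven biomes is accepted (some operations then refuse
    to run); unknown labels, duplicates and non-numeric fields are
    errors.
    """
    path = fixture_path("table1") if path is None else Path(path)
    df = pd.read_csv(path)
    required = {"biome", "density_per_ha", "mass_kg", "area_ha"}
    if df.empty or not required.issubset(df.columns):
        raise ValueError(f"{path}: expected non-empty CSV with columns {sorted(required)}")
    if df["biome"].duplicated().any():
        dupes = sorted(df.loc[df["biome"].duplicated(), "biome"])
        raise ValueError(f"{path}: duplicate biome rows {dupes}")
    unknown = sorted(set(df["biome"]) - set(CANONICAL_BIOMES))
    if unknown:
        raise ValueError(f"{path}: unknown biome label(s) {unknown}")
    params = []
    for row in df.itertuples(index=False):
        b = row.biome
        params.append(
            BiomeParams(
                biome=b,
                density=float(row.density_per_ha),
                mean_body_mass=float(row.mass_kg),
                area=float(row.area_ha),
                climate_class=getattr(row, "climate_class", ""),
                insectivore_fraction=DEFAULT_INSECTIVORE_FRACTIONS[b],
                arthropod_diet_fraction=DEFAULT_DIET_FRACTIONS[b],
                nonbreeding_multiplier=(
                    0.0 if b in TROPICAL_BIOMES else DEFAULT_NONBREEDING_MULTIPLIER
                ),
            )
        )
    return params


def read_summary_table(path: str | Path | None = None) -> list[BiomeSummary]:
    """Read per-biome consumption summaries (printed-table fixture by default).

    The subtotal is recomputed as round(mean, 1) × area, the same
    convention the pooling stage uses.
    """
    path = fixture_path("table2") if path is None else Path(path)
    df = pd.read_csv(path)
    summaries = []
    for row in df.itertuples(index=False):
        if row.biome not in CANONICAL_BIOMES:
            raise ValueError(f"{path}: unknown biome label {row.biome!r}")
        mean = float(row.mean_kg_per_ha_yr)
        area = float(row.area_ha)
        summaries.append(
            BiomeSummary(
                biome=row.biome,
                n=int(row.n_assessments),
                mean=mean,
                se=float(row.se_kg_per_ha_yr),
                area=area,
                subtotal=round_half_up(mean, 1) * area,
            )
        )
    return summaries


def read_npp_reference(path: str | Path | None = None) -> dict[str, float]:
    """Per-biome net primary production reference values (g C m⁻² yr⁻¹)."""
    path = fixture_path("npp") if path is None else Path(path)
    df = pd.read_csv(path)
    return {row.biome: float(row.npp_gC_per_m2_yr) for row in df.itertuples(index=False)}


_RECORD_COLUMNS = [
    "biome",
    "value_kg_per_ha",
    "source_type",
    "season_coverage",
    "insectivore_applied",
    "diet_applied",
    "annualized",
]


def read_records_csv(path: str | Path) -> list[ConsumptionRecord]:
    """Read per-record consumption values with their adjustment flags."""
    df = pd.read_csv(Path(path))
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for row in df.itertuples(index=False):
        records.append(
            ConsumptionRecord(
                biome=row.biome,
                value=float(row.value_kg_per_ha),
                source_type=int(row.source_type),
                season_coverage=row.season_coverage,
                flags=AdjustmentFlags(
                    bool(row.insectivore_applied),
                    bool(row.diet_applied),
                    bool(row.annualized),
                ),
            )
        )
    return records


def write_records_csv(records: Sequence[ConsumptionRecord], path: str | Path) -> None:
    """Write records in the same schema :func:`read_records_csv` expects."""
    rows = [
        {
            "biome": r.biome,
            "value_kg_per_ha": repr(r.value),
            "source_type": r.source_type,
            "season_coverage": r.season_coverage,
            "insectivore_applied": r.flags.insectivore_applied,
            "diet_applied": r.flags.diet_applied,
            "annualized": r.flags.annualized,
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=_RECORD_COLUMNS).to_csv(Path(path), index=False)


class TranscriptionPending(RuntimeError):
    """Raised when the supplementary transcription CSV holds no data yet.

    The 103 raw per-record values live in a supplementary document that
    is not machine-readable; the packaged template carries the schema so
    the records can be transcribed and dropped in later.
    """


def load_esm1_transcription(path: str | Path | None = None) -> list[ConsumptionRecord]:
    """Load transcribed supplementary records, or raise TranscriptionPending.

    By default reads the packaged (empty) template; pass the path of a
    filled-in copy to activate the supplementary-dependent checks.
    """
    path = fixture_path("esm1_template") if path is None else Path(path)
    df = pd.read_csv(path)
    missing = [c for c in _RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if df.empty:
        raise TranscriptionPending(
            f"{path} contains the schema but no transcribed records yet"
        )
    return read_records_csv(path)


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a full pipeline run.

    ``records_csv`` switches the pooling stage to per-record input;
    without it the printed per-biome summary table feeds the area
    scaling directly. ``ecophys`` holds constant overrides (the YAML
    ``ecophys:`` block). All randomness (only the synthetic generator
    uses any) enters through ``seed``.
    """

    records_csv: str | None = None
    biome_table_csv: str | None = None
    summary_csv: str | None = None
    ecophys: dict[str, float] = field(default_factory=dict)
    scenario_min_mult: float = 0.0
    scenario_max_mult: float = 0.5
    base_nonbreeding_mult: float = DEFAULT_NONBREEDING_MULTIPLIER
    npp: float = GLOBAL_TERRESTRIAL_NPP_J
    out_dir: str | None = None
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"{path}: unknown config key(s) {sorted(unknown)}")
        return cls(**raw)


def constants_from_config(overrides: Mapping[str, float]) -> EcophysConstants:
    """EcophysConstants with the given fields replaced (validated)."""
    return DEFAULT_CONSTANTS.with_overrides(**dict(overrides))


def run_full_pipeline(config: RunConfig) -> GlobalEstimate:
    """Run harmonize → pool → scale → totals → scenarios → stats.

    Deterministic for a given config; when ``out_dir`` is set, writes
    ``report.json`` plus CSV mirrors of the biomass and consumption
    tables, each carrying printed-precision and full-precision values.
    """
    constants = constants_from_config(config.ecophys)
    biome_table = read_biome_table(config.biome_table_csv)
    by_biome = {p.biome: p for p in biome_table}

    if config.records_csv is not None:
        records = read_records_csv(config.records_csv)
        harmonized: dict[str, list[ConsumptionRecord]] = {}
        for r in records:
            if r.biome not in by_biome:
                raise ValueError(f"record biome {r.biome!r} absent from biome table")
            harmonized.setdefault(r.biome, []).append(
                harmonize_record(r, by_biome[r.biome], constants)
            )
        summaries = [
            summarize_biome(harmonized[b], by_biome[b].area)
            for b in CANONICAL_BIOMES
            if b in harmonized
        ]
    else:
        summaries = read_summary_table(config.summary_csv)

    total = global_total(summaries)
    shares = biome_group_shares(summaries)
    energy, npp_frac = gross_energy_and_npp_fraction(total, constants, config.npp)
    lo, hi = scenario_bounds(
        summaries,
        base_mult=config.base_nonbreeding_mult,
        min_mult=config.scenario_min_mult,
        max_mult=config.scenario_max_mult,
    )
    estimate = GlobalEstimate(
        total=total,
        shares=shares,
        gross_energy=energy,
        npp_fraction=npp_frac,
        scenario_min=lo,
        scenario_max=hi,
    )
    if config.out_dir is not None:
        _write_reports(config, constants, biome_table, summaries, estimate)
    return estimate


def _write_reports(
    config: RunConfig,
    constants: EcophysConstants,
    biome_table: Sequence[BiomeParams],
    summaries: Sequence[BiomeSummary],
    estimate: GlobalEstimate,
) -> None:
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    biomass_rows = []
    for p in biome_table:
        sub = biome_standing_biomass(p)
        biomass_rows.append(
            {
                "biome": p.biome,
                "density_per_ha": p.density,
                "mass_kg": p.mean_body_mass,
                "area_ha": p.area,
                "biomass_kg_full_precision": repr(sub),
                "biomass_1e6_kg_printed": round_half_up(sub / 1e6),
            }
        )
    pd.DataFrame(biomass_rows).to_csv(out / "table1_biomass_report.csv", index=False)

    summary_rows = []
    for s in summaries:
        summary_rows.append(
            {
                "biome": s.biome,
                "n": s.n,
                "mean_kg_per_ha_yr_full_precision": repr(s.mean),
                "mean_kg_per_ha_yr_printed": s.mean_printed,
                "se_kg_per_ha_yr": repr(s.se),
                "area_ha": s.area,
                "subtotal_kg_yr_full_precision": repr(s.subtotal),
                "subtotal_1e6_kg_yr_printed": round_half_up(s.subtotal / 1e6),
            }
        )
    pd.DataFrame(summary_rows).to_csv(out / "table2_consumption_report.csv", index=False)

    report: dict[str, Any] = {
        "constants": dataclasses.asdict(constants),
        "seed": config.seed,
        "standing_biomass": {
            "global_kg": global_standing_biomass(biome_table),
            "global_1e6_kg_printed": round_half_up(
                global_standing_biomass(biome_table) / 1e6
            ),
            "insectivore_kg": insectivore_standing_biomass(biome_table),
            "insectivore_million_tons_printed": round_half_up(
                insectivore_standing_biomass(biome_table) / 1e9
            ),
        },
        "consumption": {
            "global_kg_yr": estimate.total,
            "global_1e6_kg_yr_printed": round_half_up(estimate.total / 1e6),
            "shares": estimate.shares,
            "shares_pct_printed": {
                k: round_half_up(100 * v) for k, v in estimate.shares.items()
            },
            "gross_energy_J_yr": estimate.gross_energy,
            "npp_fraction": estimate.npp_fraction,
            "npp_fraction_pct_printed": round_half_up(100 * estimate.npp_fraction, 2),
            "scenario_min_kg_yr": estimate.scenario_min,
            "scenario_max_kg_yr": estimate.scenario_max,
        },
        "stopover_tons_yr": stopover_consumption(constants=constants),
        "npp_spearman": consumption_npp_correlation(
            [s.mean for s in summaries],
            [read_npp_reference()[s.biome] for s in summaries],
        ),
    }
    (out / "report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )


def stats_from_records(
    records: Sequence[ConsumptionRecord], p_adjust: str = "none"
):
    """Omnibus + pairwise rank tests on records grouped by biome."""
    groups: dict[str, list[float]] = {}
    for r in records:
        groups.setdefault(r.biome, []).append(r.value)
    return dunn_test(GroupedSamples.from_mapping(groups), p_adjust=p_adjust)
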