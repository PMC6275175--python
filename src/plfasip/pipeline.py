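"""End-to-end analysis: read -> FAME-correct -> excess 13C -> %litter ->
group aggregation -> respiration -> succession -> ordination -> report.

The stage order is fixed.  Every flagged value (negative excess, %litter
outside [0, 100]) is preserved and itemized in the QC table; nothing is
clipped.  Identical inputs and configuration produce identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from . import community, io
from .errors import MissingReferenceError, SchemaError
from .gasflux import rates_from_table
from .isotope import (
    DEFAULT_CONSTANTS,
    DEFAULT_ENDMEMBERS,
    IsotopeConstants,
    MixingEndmembers,
    correct_fame_delta,
    delta_to_atom_fraction,
)
from .ordination import OrdinationResult, ordinate
from .succession import SuccessionResult, normalize_excess, succession_order

TableLike = Union[pd.DataFrame, str, Path]


@dataclass
class RunConfig:
    """Everything that parameterizes one pipeline run (fully serializable)."""

    catalog_path: Optional[str] = None
    constants: IsotopeConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)
    endmembers: MixingEndmembers = field(default_factory=lambda: DEFAULT_ENDMEMBERS)
    delta_methanol: float = -40.0
    mixing_mode: str = "delta_linear"      # or "atom_fraction" (sensitivity)
    sd_ddof: int = 1                       # z-score convention (1 = sample sd)
    succession_pooling: str = "per_field"  # or "pooled"
    reference_treatment: str = "no_litter_control"  # two-pool model reference
    include_ordination: bool = True
    include_gas: bool = True
    ordination_scale: str = "covariance"
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["constants"] = {"r_vpdb": self.constants.r_vpdb}
        d["endmembers"] = {
            "delta_litter": self.endmembers.delta_litter,
            "delta_soil": self.endmembers.delta_soil,
        }
        return d


@dataclass
class PipelineResult:
    """The full result bundle of one run."""

    per_biomarker: pd.DataFrame      # labeled rows with excess / %litter / flags
    per_replicate: pd.DataFrame      # group x sample aggregates
    group_series: pd.DataFrame       # group x field x day means
    respiration: Optional[pd.DataFrame]
    succession: SuccessionResult
    normalized_series: pd.DataFrame  # z-scored group excess courses
    ordination: Optional[OrdinationResult]
    qc_flags: pd.DataFrame
    metadata: dict


def _as_frame(table: TableLike, reader) -> pd.DataFrame:
    if isinstance(table, pd.DataFrame):
        return table.copy()
    return reader(table)


def _pct_litter(delta_sample, delta_reference, config: RunConfig) -> np.ndarray:
    span = config.endmembers.delta_litter - config.endmembers.delta_soil
    if config.mixing_mode == "delta_linear":
        return 100.0 * (np.asarray(delta_sample, float)
                        - np.asarray(delta_reference, float)) / span
    if config.mixing_mode == "atom_fraction":
        af = lambda d: np.asarray(delta_to_atom_fraction(d, config.constants))
        span_af = (af(config.endmembers.delta_litter)
                   - af(config.endmembers.delta_soil))
        return 100.0 * (af(delta_sample) - af(delta_reference)) / span_af
    raise SchemaError(f"unknown mixing_mode {config.mixing_mode!r}")


def _correct_and_reference(
    measurements: pd.DataFrame, catalog: pd.DataFrame, config: RunConfig
) -> tuple[pd.DataFrame, pd.DataFrame, list[str]]:
    """FAME-correct all deltas and attach the matched control reference."""
    df = measurements.copy()
    group, unknown = community.assign_groups(df["biomarker"], catalog)
    df["group"] = group
    n_carbons = df["biomarker"].map(catalog["n_carbons"])
    needs_parse = n_carbons.isna()
    if needs_parse.any():
        n_carbons = n_carbons.copy()
        n_carbons[needs_parse] = [
            community.parse_n_carbons(b) for b in df.loc[needs_parse, "biomarker"]
        ]
    df["n_carbons"] = n_carbons.astype(int)
    df["delta_plfa"] = correct_fame_delta(
        df["delta13C_fame_permil"].to_numpy(float),
        config.delta_methanol,
        df["n_carbons"].to_numpy(float),
    )

    ctrl = df[df["treatment"] == config.reference_treatment]
    if ctrl.empty:
        raise MissingReferenceError(
            f"no {config.reference_treatment!r} samples present: cannot form "
            "excess 13C or the two-pool reference"
        )
    ref = (
        ctrl.groupby(["field", "day", "biomarker"], as_index=False)["delta_plfa"]
        .mean()
        .rename(columns={"delta_plfa": "delta_reference"})
    )
    labeled = df[df["treatment"] == "labeled"].merge(
        ref, on=["field", "day", "biomarker"], how="left"
    )
    orphans = labeled[labeled["delta_reference"].isna()]
    if not orphans.empty:
        missing = (
            orphans[["field", "day", "biomarker"]].drop_duplicates()
            .to_records(index=False).tolist()
        )
        raise MissingReferenceError(
            f"no matched {config.reference_treatment!r} for (field, day, biomarker): "
            f"{missing[:10]}" + (" ..." if len(missing) > 10 else "")
        )
    return df, labeled, unknown


def _aggregate_groups(labeled: pd.DataFrame) -> pd.DataFrame:
    """Per-sample group totals, including the all-biomarker 'total' pool."""
    keys = ["sample_id", "field", "stage", "day"]
    per_group = (
        labeled.groupby(keys + ["group"], as_index=False)
        .agg(
            biomass=("amount_nmolC_per_g", "sum"),
            excess_13c=("excess_13c", "sum"),
            litter_biomass=("litter_biomass", "sum"),
        )
    )
    total = (
        labeled.groupby(keys, as_index=False)
        .agg(
            biomass=("amount_nmolC_per_g", "sum"),
            excess_13c=("excess_13c", "sum"),
            litter_biomass=("litter_biomass", "sum"),
        )
        .assign(group=community.TOTAL)
    )
    out = pd.concat([per_group, total], ignore_index=True)
    out["pct_litter"] = 100.0 * out["litter_biomass"] / out["biomass"]
    return out


def _succession_input(
    group_series: pd.DataFrame, config: RunConfig
) -> tuple[dict, pd.DataFrame]:
    """Group -> (days, values) series for ordering, plus the normalized table.

    per_field mode z-scores each (group, field) course over the incubation
    and averages the z-scores across fields; pooled mode averages raw excess
    across fields first and z-scores once.
    """
    sub = group_series[group_series["group"].isin(community.GROUPS)]
    rows = []
    if config.succession_pooling == "per_field":
        for (group, fld), g in sub.groupby(["group", "field"]):
            g = g.sort_values("day")
            z = normalize_excess(g["excess_13c"].to_numpy(), ddof=config.sd_ddof)
            rows.append(pd.DataFrame({
                "group": group, "field": fld, "day": g["day"].to_numpy(), "z": z,
            }))
        norm = pd.concat(rows, ignore_index=True)
        mean_norm = norm.groupby(["group", "day"], as_index=False)["z"].mean()
    elif config.succession_pooling == "pooled":
        pooled = sub.groupby(["group", "day"], as_index=False)["excess_13c"].mean()
        for group, g in pooled.groupby("group"):
            g = g.sort_values("day")
            z = normalize_excess(g["excess_13c"].to_numpy(), ddof=config.sd_ddof)
            rows.append(pd.DataFrame({
                "group": group, "field": "pooled", "day": g["day"].to_numpy(), "z": z,
            }))
        norm = pd.concat(rows, ignore_index=True)
        mean_norm = norm.groupby(["group", "day"], as_index=False)["z"].mean()
    else:
        raise SchemaError(f"unknown succession_pooling {config.succession_pooling!r}")
    series = {
        group: (g.sort_values("day")["day"].to_numpy(),
                g.sort_values("day")["z"].to_numpy())
        for group, g in mean_norm.groupby("group")
    }
    return series, mean_norm


def _respiration_table(gas: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    rates = rates_from_table(gas, config.constants)
    ctrl = rates[rates["treatment"] == config.reference_treatment]
    if ctrl.empty:
        raise MissingReferenceError(
            f"no {config.reference_treatment!r} bottles in the gas table"
        )
    ref = (
        ctrl.groupby(["field", "day"], as_index=False)
        .agg(reference_evolved_delta=("evolved_delta", "mean"),
             control_rate=("total_rate", "mean"))
    )
    labeled = rates[rates["treatment"] == "labeled"].merge(
        ref, on=["field", "day"], how="left"
    )
    orphans = labeled[labeled["reference_evolved_delta"].isna()]
    if not orphans.empty:
        missing = orphans[["field", "day"]].drop_duplicates().to_records(index=False).tolist()
        raise MissingReferenceError(
            f"no matched control bottle for (field, day): {missing}"
        )
    labeled["pct_litter"] = _pct_litter(
        labeled["evolved_delta"], labeled["reference_evolved_delta"], config
    )
    labeled["litter_rate"] = labeled["pct_litter"] / 100.0 * labeled["total_rate"]
    labeled["flag_out_of_range"] = (labeled["pct_litter"] < 0) | (labeled["pct_litter"] > 100)
    summary = (
        labeled.groupby(["field", "stage", "day"], as_index=False)
        .agg(
            total_rate=("total_rate", "mean"),
            c13_rate=("c13_rate", "mean"),
            evolved_delta=("evolved_delta", "mean"),
            pct_litter=("pct_litter", "mean"),
            litter_rate=("litter_rate", "mean"),
            control_rate=("control_rate", "first"),
            n_bottles=("bottle_id", "count"),
            n_flagged=("flag_out_of_range", "sum"),
        )
    )
    return summary


def run_pipeline(
    measurements: TableLike,
    gas: Optional[TableLike] = None,
    config: Optional[RunConfig] = None,
) -> PipelineResult:
    """Run the full PLFA-SIP analysis on one dataset.

    ``measurements`` and ``gas`` may be data frames or TSV paths with the
    documented schemas.  Returns the full result bundle; use
    :func:`write_results` to materialize it.
    """
    config = config or RunConfig()
    catalog = community.load_catalog(config.catalog_path)
    meas = _as_frame(measurements, io.read_measurements)

    # 1-2: FAME correction and control matching
    corrected, labeled, unknown_biomarkers = _correct_and_reference(
        meas, catalog, config
    )

    # 3: excess 13C per biomarker (never clipped)
    af_sample = np.asarray(
        delta_to_atom_fraction(labeled["delta_plfa"].to_numpy(float), config.constants)
    )
    af_ref = np.asarray(
        delta_to_atom_fraction(labeled["delta_reference"].to_numpy(float), config.constants)
    )
    labeled["excess_13c"] = (af_sample - af_ref) * labeled["amount_nmolC_per_g"].to_numpy(float)

    # 4: two-pool litter fractions per biomarker
    labeled["pct_litter"] = _pct_litter(
        labeled["delta_plfa"], labeled["delta_reference"], config
    )
    labeled["litter_biomass"] = labeled["pct_litter"] / 100.0 * labeled["amount_nmolC_per_g"]
    labeled["flag_negative_excess"] = labeled["excess_13c"] < 0
    labeled["flag_pct_out_of_range"] = (
        (labeled["pct_litter"] < 0) | (labeled["pct_litter"] > 100)
    )

    # 5: group aggregation (replicate level, then field x day means)
    per_replicate = _aggregate_groups(labeled)
    group_series = (
        per_replicate.groupby(["field", "stage", "day", "group"], as_index=False)
        .agg(
            biomass=("biomass", "mean"),
            excess_13c=("excess_13c", "mean"),
            litter_biomass=("litter_biomass", "mean"),
            pct_litter=("pct_litter", "mean"),
            n_replicates=("sample_id", "nunique"),
        )
    )

    # 6: respiration
    respiration = None
    if config.include_gas and gas is not None:
        gas_df = _as_frame(gas, io.read_gas)
        respiration = _respiration_table(gas_df, config)

    # 7: succession
    series, normalized = _succession_input(group_series, config)
    succession = succession_order(series, ddof=config.sd_ddof)

    # 8: ordination of community composition (all samples, all biomarkers)
    ordination = None
    if config.include_ordination:
        rel = community.relative_abundance_table(
            corrected.rename(columns={"amount_nmolC_per_g": "amount"})
        )
        matrix = rel.pivot_table(
            index="sample_id", columns="biomarker", values="rel_abundance_pct"
        )
        ordination = ordinate(matrix, scale=config.ordination_scale)

    # 9: QC report
    qc_rows = labeled.loc[
        labeled["flag_negative_excess"] | labeled["flag_pct_out_of_range"],
        ["sample_id", "field", "day", "biomarker", "excess_13c", "pct_litter",
         "flag_negative_excess", "flag_pct_out_of_range"],
    ].reset_index(drop=True)

    cfg_dict = config.to_dict()
    metadata = {
        "config": cfg_dict,
        "config_hash": io.config_hash(cfg_dict),
        "n_measurements": int(len(meas)),
        "n_labeled_rows": int(len(labeled)),
        "unknown_biomarkers": unknown_biomarkers,
        "n_qc_flags": int(len(qc_rows)),
        "succession_order": list(succession.order),
        "succession_ties": [list(t) for t in succession.ties],
        "stage_sequence": [
            "fame_correction", "excess_13c", "litter_fraction",
            "group_aggregation", "respiration", "succession", "ordination", "report",
        ],
    }
    return PipelineResult(
        per_biomarker=labeled,
        per_replicate=per_replicate,
        group_series=group_series,
        respiration=respiration,
        succession=succession,
        normalized_series=normalized,
        ordination=ordination,
        qc_flags=qc_rows,
        metadata=metadata,
    )


def write_results(result: PipelineResult, outdir) -> None:
    """Materialize a result bundle as TSV tables plus run metadata JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    io.write_table(result.group_series, outdir / "group_series.tsv", {
        "biomass": "nmol_C_per_g_dry_soil",
        "excess_13c": "nmol_13C_per_g_dry_soil",
        "pct_litter": "percent",
    })
    if result.respiration is not None:
        io.write_table(result.respiration, outdir / "respiration.tsv", {
            "total_rate": "ug_C_per_g_dry_soil_per_day",
            "c13_rate": "ug_13C_per_g_dry_soil_per_day",
            "pct_litter": "percent",
        })
    succ = pd.DataFrame(
        [
            {
                "rank": i + 1,
                "group": p.group,
                "peak_day": p.peak_day,
                "tied_with_next": any(p.group in t for t in result.succession.ties),
                "half_max_day": p.half_max_day,
            }
            for i, p in enumerate(result.succession.peaks)
        ]
    )
    io.write_table(succ, outdir / "succession.tsv")
    io.write_table(result.normalized_series, outdir / "normalized_series.tsv")
    if result.ordination is not None:
        io.write_table(
            result.ordination.scores.reset_index(names="sample_id"),
            outdir / "ordination_scores.tsv",
        )
        io.write_table(
            result.ordination.loadings.reset_index(names="biomarker"),
            outdir / "ordination_loadings.tsv",
        )
        result.metadata["ordination_variance_explained_pct"] = [
            float(v) for v in result.ordination.variance_explained_pct
        ]
    io.write_table(result.qc_flags, outdir / "qc_flags.tsv")
    io.write_run_metadata(result.metadata, outdir / "run_metadata.json")
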