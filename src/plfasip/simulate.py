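"""Seeded synthetic litter-amendment incubations with known ground truth.

The generator emulates a 13C-labeled litter decomposition experiment:
six grassland fields (three recently abandoned from agriculture, three
long-term abandoned), destructive harvests at days 1, 3, 7, 14, 28 and 56,
and per field and day three labeled bottles plus an unlabeled-litter and a
no-litter control.  Litter-derived carbon enters each microbial group's
PLFA pool along a rise-then-decay (gamma-shaped) uptake curve with a
group-specific peak day; biomarker delta13C values mix the native pool
(soil endmember) with the litter-derived pool on the delta-linear two-pool
model, and are then pushed through the FAME derivatization forward model so
the analysis must apply the methanol correction to recover them.  Headspace
gas observations are built by exact mass balance, including the t0
withdrawal / N2-refill dilution event.

Every dataset is emitted together with its noise-free truth (litter-derived
biomass and percent per group, production rate and source delta per bottle,
peak day per group), against which pipeline recovery is scored.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import community
from .errors import ConfigError
from .gasflux import default_headspace_volume, ppm_to_ug_c_per_ml
from .isotope import (
    DEFAULT_CONSTANTS,
    IsotopeConstants,
    MixingEndmembers,
    delta_to_atom_fraction,
    fame_forward_delta,
    mix_delta,
)

#: Carbon-mass conversion: ug C per nmol C.
UG_PER_NMOL_C = 12.011e-3



@dataclass(frozen=True)
class GroupKinetics:
    """Litter-13C uptake curve for one functional group.

    The curve rises as a gamma shape peaking at ``peak_day`` (value 1 at the
    peak) and decays exponentially afterwards with time constant
    ``decay_tau`` (days); ``rise_shape`` controls how steep the rise is
    (larger = later, steeper rise).  ``max_litter_biomass`` (nmol C g^-1) is
    the litter-derived PLFA carbon at the peak.
    """

    peak_day: float
    rise_shape: float
    decay_tau: float
    max_litter_biomass: float

    def curve(self, t):
        """Fraction of maximum litter-derived biomass present at day t."""
        t = np.asarray(t, dtype=float)
        p, a, tau = self.peak_day, self.rise_shape, self.decay_tau
        rise = (t / p) ** a * np.exp(a * (1.0 - t / p))
        decay = np.exp(-(t - p) / tau)
        out = np.where(t <= p, rise, decay)
        return out if out.ndim else float(out)

    def litter_biomass(self, t):
        return self.max_litter_biomass * self.curve(t)


# Peak order fungi -> gram-negative -> gram-positive/actinomycetes (tied at
# day 14, gram-positives rising faster, actinomycetes plateauing afterwards)
# -> micro-fauna; amplitudes sized so the fungal pool dominates the early
# litter-derived biomass.
DEFAULT_KINETICS = {
    "fungi": GroupKinetics(1.0, 1.5, 3.0, 800.0),
    "gram_negative": GroupKinetics(3.0, 2.0, 8.0, 240.0),
    "gram_positive": GroupKinetics(14.0, 2.0, 12.0, 100.0),
    "actinomycetes": GroupKinetics(14.0, 3.0, 60.0, 22.0),
    "microfauna": GroupKinetics(28.0, 2.5, 40.0, 12.0),
    "unassigned": GroupKinetics(3.0, 2.0, 20.0, 300.0),
}

# Baseline (pre-amendment) group biomass, nmol C g^-1 dry soil, per
# land-abandonment stage; long-term abandoned soils carry ~35% more biomass.
DEFAULT_BASELINE = {
    "recent": {
        "fungi": 18.3,
        "gram_negative": 182.4,
        "gram_positive": 190.2,
        "actinomycetes": 70.7,
        "microfauna": 9.4,
        "unassigned": 401.0,
    },
    "long_term": {
        "fungi": 22.1,
        "gram_negative": 254.9,
        "gram_positive": 261.6,
        "actinomycetes": 110.2,
        "microfauna": 13.0,
        "unassigned": 515.0,
    },
}


@dataclass(frozen=True)
class RespirationKinetics:
    """Respiration of one stage: basal rate plus a decaying litter pulse.

    rate(t) = basal + pulse * exp(-decay_rate * t); a fraction
    ``litter_share`` of the pulse is litter-derived carbon (the rest is
    primed native mineralization).  Units: ug C g^-1 dry soil day^-1.
    """

    basal: float
    pulse: float
    decay_rate: float
    litter_share: float

    def total_rate(self, t):
        t = np.asarray(t, dtype=float)
        out = self.basal + self.pulse * np.exp(-self.decay_rate * t)
        return out if out.ndim else float(out)

    def litter_rate(self, t):
        t = np.asarray(t, dtype=float)
        out = self.litter_share * self.pulse * np.exp(-self.decay_rate * t)
        return out if out.ndim else float(out)

    def cumulative_litter_c(self, t_end: float) -> float:
        """Litter-derived CO2-C respired from day 0 to t_end (ug C g^-1)."""
        k = self.decay_rate
        return self.litter_share * self.pulse / k * (1.0 - np.exp(-k * t_end))


DEFAULT_RESPIRATION = {
    # day-1 totals ~92 and ~100 vs basal 7.2 / 8.6: >10x increase on day 1
    "recent": RespirationKinetics(basal=7.2, pulse=115.0, decay_rate=0.30, litter_share=0.55),
    "long_term": RespirationKinetics(basal=8.6, pulse=123.0, decay_rate=0.30, litter_share=0.55),
}


@dataclass
class ScenarioConfig:
    """Full specification of one synthetic incubation.

    The defaults are the study conditions the pipeline is designed around:
    3 + 3 fields, harvests at days 1-56, 3 labeled replicates plus two
    controls per field and day, litter at 904.0 permil vs soil at
    -25.7 permil, 333 mL bottles with 50 g dry soil closed for 4.5 h with a
    15 mL t0 sample replaced by N2.
    """

    fields_per_stage: int = 3
    days: tuple = (1, 3, 7, 14, 28, 56)
    n_labeled: int = 3
    endmembers: MixingEndmembers = field(
        default_factory=lambda: MixingEndmembers(904.0, -25.7)
    )
    delta_methanol: float = -40.0
    kinetics: dict = field(default_factory=lambda: dict(DEFAULT_KINETICS))
    baseline: dict = field(default_factory=lambda: {
        stage: dict(groups) for stage, groups in DEFAULT_BASELINE.items()
    })
    respiration: dict = field(default_factory=lambda: dict(DEFAULT_RESPIRATION))
    # field-to-field lognormal spread of baseline biomass and basal respiration
    field_cv: float = 0.10
    # measurement noise
    delta_sd: float = 10.0          # permil, additive Gaussian (IRMS)
    amount_cv: float = 0.10         # lognormal multiplicative (GC-FID)
    co2_cv: float = 0.02            # lognormal multiplicative on gas concentrations
    gas_delta_sd: float = 10.0      # permil, additive Gaussian on gas deltas
    # chamber geometry and protocol
    bottle_volume_ml: float = 333.0
    soil_dry_mass_g: float = 50.0
    bulk_density_g_cm3: float = 1.4
    sample_volume_ml: float = 15.0
    closure_hours: float = 4.5
    ambient_co2_ppm: float = 400.0
    ambient_delta: float = -8.5
    incubation_temp_c: float = 17.5
    # litter amendment (for the carbon budget)
    litter_mass_g: float = 0.5
    litter_c_fraction: float = 0.45
    constants: IsotopeConstants = field(default_factory=lambda: DEFAULT_CONSTANTS)
    seed: int = 0

    def validate(self) -> None:
        if self.fields_per_stage < 1 or self.n_labeled < 1:
            raise ConfigError("need at least one field per stage and one labeled replicate")
        if len(self.days) < 2 or any(d <= 0 for d in self.days):
            raise ConfigError("days must be >= 2 positive harvest points")
        for name, kin in self.kinetics.items():
            if not (min(self.days) <= kin.peak_day <= max(self.days)):
                raise ConfigError(
                    f"{name} peak day {kin.peak_day} outside harvest grid {self.days}"
                )
            if kin.max_litter_biomass < 0 or kin.decay_tau <= 0 or kin.rise_shape <= 0:
                raise ConfigError(f"invalid kinetics for {name}")
        for v in (self.delta_sd, self.amount_cv, self.co2_cv, self.gas_delta_sd, self.field_cv):
            if v < 0:
                raise ConfigError("noise parameters must be >= 0")
        if self.sample_volume_ml >= self.headspace_volume_ml:
            raise ConfigError("sample volume must be smaller than headspace")

    @property
    def headspace_volume_ml(self) -> float:
        return default_headspace_volume(
            self.bottle_volume_ml, self.soil_dry_mass_g, self.bulk_density_g_cm3
        )

    @property
    def litter_c_input_ug_per_g(self) -> float:
        """Litter carbon added per g dry soil (ug C g^-1)."""
        return self.litter_mass_g * self.litter_c_fraction / self.soil_dry_mass_g * 1e6

    @property
    def stages(self) -> tuple:
        return tuple(self.baseline)

    def field_ids(self) -> list[tuple[str, str]]:
        """(field id, stage) pairs, e.g. R1..R3 recent, L1..L3 long_term."""
        out = []
        for stage in self.stages:
            prefix = stage[0].upper()
            out += [(f"{prefix}{i + 1}", stage) for i in range(self.fields_per_stage)]
        return out

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["endmembers"] = {
            "delta_litter": self.endmembers.delta_litter,
            "delta_soil": self.endmembers.delta_soil,
        }
        d["constants"] = {"r_vpdb": self.constants.r_vpdb}
        d["kinetics"] = {g: dataclasses.asdict(k) for g, k in self.kinetics.items()}
        d["respiration"] = {s: dataclasses.asdict(r) for s, r in self.respiration.items()}
        return d


def default_scenario(seed: int = 0) -> ScenarioConfig:
    """The documented default incubation scenario (validated, deterministic)."""
    cfg = ScenarioConfig(seed=seed)
    cfg.validate()
    return cfg


@dataclass
class SimulatedDataset:
    """A generated incubation: measurement tables plus noise-free truth."""

    measurements: pd.DataFrame  # long PLFA table (FAME deltas, pre-correction)
    gas: pd.DataFrame           # two-point chamber observations
    truth_groups: pd.DataFrame  # per (field, group, day) litter biomass & pct
    truth_gas: pd.DataFrame     # per (field, treatment, day) rates & source delta
    truth_peaks: dict           # group -> configured peak day
    config: ScenarioConfig


def _lognormal_multipliers(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Mean-1 lognormal multipliers with the given coefficient of variation."""
    if cv == 0:
        return np.ones(size)
    sigma = np.sqrt(np.log1p(cv**2))
    return rng.lognormal(mean=-(sigma**2) / 2.0, sigma=sigma, size=size)


def _bottles(config: ScenarioConfig) -> list[tuple[str, int]]:
    out = [("labeled", r + 1) for r in range(config.n_labeled)]
    out += [("unlabeled_control", 1), ("no_litter_control", 1)]
    return out


def simulate_incubation(config: Optional[ScenarioConfig] = None) -> SimulatedDataset:
    """Generate one complete synthetic incubation dataset plus its truth.

    Deterministic: identical configs (including seed) produce identical
    tables.  Substreams for field effects, the PLFA table and the gas table
    are derived independently from the seed, so adding observations to one
    table never shifts the draws of another.
    """
    if config is None:
        config = default_scenario()
    config.validate()

    rng_fields = np.random.default_rng([config.seed, 0])
    rng_plfa = np.random.default_rng([config.seed, 1])
    rng_gas = np.random.default_rng([config.seed, 2])

    catalog = community.load_catalog()
    fields = config.field_ids()
    field_mult = dict(
        zip([f for f, _ in fields],
            _lognormal_multipliers(rng_fields, config.field_cv, len(fields)))
    )
    stage_of = dict(fields)
    days = np.asarray(config.days, dtype=float)

    # --- PLFA table -------------------------------------------------------
    bottles = _bottles(config)
    biomarkers = list(catalog.index)
    rows = pd.MultiIndex.from_product(
        [
            [f for f, _ in fields],
            config.days,
            range(len(bottles)),
            biomarkers,
        ],
        names=["field", "day", "bottle_idx", "biomarker"],
    ).to_frame(index=False)
    rows["stage"] = rows["field"].map(stage_of)
    rows["treatment"] = rows["bottle_idx"].map(lambda i: bottles[i][0])
    rows["replicate"] = rows["bottle_idx"].map(lambda i: bottles[i][1])
    rows["group"] = rows["biomarker"].map(catalog["group"])
    rows["n_carbons"] = rows["biomarker"].map(catalog["n_carbons"])
    group_sizes = catalog["group"].value_counts()
    n_members = rows["group"].map(group_sizes).to_numpy(dtype=float)

    # group-level litter-derived pool on the harvest grid
    litter_by_group_day = {
        (g, d): config.kinetics[g].litter_biomass(d) if g in config.kinetics else 0.0
        for g in community.GROUP_LABELS
        for d in config.days
    }
    litter_group = np.array(
        [litter_by_group_day[(g, d)] for g, d in zip(rows["group"], rows["day"])]
    )
    baseline_group = np.array(
        [config.baseline[s][g] for s, g in zip(rows["stage"], rows["group"])]
    ) * rows["field"].map(field_mult).to_numpy()

    has_litter = (rows["treatment"] != "no_litter_control").to_numpy()
    is_labeled = (rows["treatment"] == "labeled").to_numpy()

    litter_biomarker = np.where(has_litter, litter_group / n_members, 0.0)
    baseline_biomarker = baseline_group / n_members
    amount_true = baseline_biomarker + litter_biomarker

    frac_litter = np.where(
        is_labeled & (amount_true > 0), litter_biomarker / amount_true, 0.0
    )
    delta_plfa_true = mix_delta(frac_litter, config.endmembers)
    delta_fame_true = fame_forward_delta(
        delta_plfa_true, config.delta_methanol, rows["n_carbons"].to_numpy(float)
    )

    amount = amount_true * _lognormal_multipliers(
        rng_plfa, config.amount_cv, len(rows)
    )
    delta_fame = delta_fame_true + (
        rng_plfa.normal(0.0, config.delta_sd, len(rows)) if config.delta_sd > 0
        else 0.0
    )

    measurements = pd.DataFrame(
        {
            "sample_id": (
                rows["field"] + "_d" + rows["day"].astype(str) + "_"
                + rows["treatment"] + rows["replicate"].astype(str)
            ),
            "field": rows["field"],
            "stage": rows["stage"],
            "treatment": rows["treatment"],
            "day": rows["day"],
            "biomarker": rows["biomarker"],
            "amount_nmolC_per_g": amount,
            "delta13C_fame_permil": delta_fame,
        }
    )

    # --- truth per (field, group, day) ------------------------------------
    tg = pd.MultiIndex.from_product(
        [[f for f, _ in fields], list(community.GROUP_LABELS), config.days],
        names=["field", "group", "day"],
    ).to_frame(index=False)
    tg["stage"] = tg["field"].map(stage_of)
    tg["true_litter_biomass"] = [
        litter_by_group_day[(g, d)] for g, d in zip(tg["group"], tg["day"])
    ]
    tg_baseline = np.array(
        [config.baseline[s][g] for s, g in zip(tg["stage"], tg["group"])]
    ) * tg["field"].map(field_mult).to_numpy()
    tg["true_baseline_biomass"] = tg_baseline
    tg["true_total_biomass"] = tg_baseline + tg["true_litter_biomass"]
    tg["true_pct_litter"] = 100.0 * tg["true_litter_biomass"] / tg["true_total_biomass"]
    truth_groups = tg[
        ["field", "stage", "group", "day", "true_baseline_biomass",
         "true_litter_biomass", "true_total_biomass", "true_pct_litter"]
    ]

    # --- gas table by exact chamber mass balance --------------------------
    headspace = config.headspace_volume_ml
    dilution = (headspace - config.sample_volume_ml) / headspace
    c_ambient = ppm_to_ug_c_per_ml(
        config.ambient_co2_ppm, config.incubation_temp_c
    )
    af_ambient = delta_to_atom_fraction(config.ambient_delta, config.constants)

    grow = pd.MultiIndex.from_product(
        [[f for f, _ in fields], config.days, range(len(bottles))],
        names=["field", "day", "bottle_idx"],
    ).to_frame(index=False)
    grow["stage"] = grow["field"].map(stage_of)
    grow["treatment"] = grow["bottle_idx"].map(lambda i: bottles[i][0])
    grow["replicate"] = grow["bottle_idx"].map(lambda i: bottles[i][1])
    resp = {s: config.respiration[s] for s in config.stages}
    basal = np.array([resp[s].basal for s in grow["stage"]]) * grow["field"].map(
        field_mult
    ).to_numpy()
    day_arr = grow["day"].to_numpy(dtype=float)
    pulse = np.array(
        [resp[s].pulse * np.exp(-resp[s].decay_rate * d)
         for s, d in zip(grow["stage"], day_arr)]
    )
    litter_rate = np.array(
        [resp[s].litter_share for s in grow["stage"]]
    ) * pulse
    g_has_litter = (grow["treatment"] != "no_litter_control").to_numpy()
    g_is_labeled = (grow["treatment"] == "labeled").to_numpy()
    total_rate = basal + np.where(g_has_litter, pulse, 0.0)
    litter_rate = np.where(g_is_labeled, litter_rate, 0.0)
    frac_resp = np.where(total_rate > 0, litter_rate / total_rate, 0.0)
    source_delta = mix_delta(frac_resp, config.endmembers)
    af_source = np.asarray(delta_to_atom_fraction(source_delta, config.constants))

    accumulated = (
        total_rate * config.soil_dry_mass_g * (config.closure_hours / 24.0) / headspace
    )  # ug C per mL added to the headspace between t0+ and t1
    c0_true = np.full(len(grow), c_ambient)
    c1_true = c0_true * dilution + accumulated
    af1_true = (af_ambient * c0_true * dilution + af_source * accumulated) / c1_true
    delta0_true = np.full(len(grow), config.ambient_delta)
    r = af1_true / (1.0 - af1_true)
    delta1_true = (r / config.constants.r_vpdb - 1.0) * 1000.0

    c0 = c0_true * _lognormal_multipliers(rng_gas, config.co2_cv, len(grow))
    c1 = c1_true * _lognormal_multipliers(rng_gas, config.co2_cv, len(grow))
    if config.gas_delta_sd > 0:
        delta0 = delta0_true + rng_gas.normal(0.0, config.gas_delta_sd, len(grow))
        delta1 = delta1_true + rng_gas.normal(0.0, config.gas_delta_sd, len(grow))
    else:
        delta0, delta1 = delta0_true, delta1_true

    gas = pd.DataFrame(
        {
            "bottle_id": (
                grow["field"] + "_d" + grow["day"].astype(str) + "_"
                + grow["treatment"] + grow["replicate"].astype(str)
            ),
            "field": grow["field"],
            "stage": grow["stage"],
            "treatment": grow["treatment"],
            "day": grow["day"],
            "t0_h": 0.0,
            "t1_h": config.closure_hours,
            "co2_t0": c0,
            "co2_t1": c1,
            "delta13C_t0": delta0,
            "delta13C_t1": delta1,
            "headspace_ml": headspace,
            "sample_ml": config.sample_volume_ml,
            "soil_dw_g": config.soil_dry_mass_g,
        }
    )

    truth_gas = pd.DataFrame(
        {
            "field": grow["field"],
            "stage": grow["stage"],
            "treatment": grow["treatment"],
            "replicate": grow["replicate"],
            "day": grow["day"],
            "true_total_rate": total_rate,
            "true_litter_rate": litter_rate,
            "true_pct_litter": 100.0 * frac_resp,
            "true_source_delta": source_delta,
        }
    )

    truth_peaks = {
        g: float(k.peak_day) for g, k in config.kinetics.items() if g != "unassigned"
    }
    return SimulatedDataset(
        measurements, gas, truth_groups, truth_gas, truth_peaks, config
    )


def litter_carbon_budget(config: ScenarioConfig) -> dict:
    """Litter-C accounting per bottle (ug C g^-1 dry soil).

    The generator must never create more litter-derived carbon than was
    added: peak litter-derived PLFA-C plus cumulative litter-derived CO2-C
    must stay below the litter C input.  (PLFA-C is itself only a small
    biomarker fraction of total microbial biomass C, so the headroom is
    deliberately large.)
    """
    t = np.linspace(min(config.days) * 1e-3, max(config.days), 2001)
    biomass_c = np.zeros_like(t)
    for g, kin in config.kinetics.items():
        biomass_c += kin.litter_biomass(t) * UG_PER_NMOL_C
    budget = {}
    for stage in config.stages:
        resp = config.respiration[stage]
        cum_co2 = resp.cumulative_litter_c(max(config.days))
        budget[stage] = {
            "litter_c_input": config.litter_c_input_ug_per_g,
            "peak_litter_plfa_c": float(biomass_c.max()),
            "cumulative_litter_co2_c": float(cum_co2),
            "total_litter_derived_c": float(biomass_c.max() + cum_co2),
        }
    return budget
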