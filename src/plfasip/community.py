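"""PLFA biomarker -> microbial functional group mapping and aggregation.

Membrane phospholipid fatty acids fingerprint the living microbial
community: 18:2w6 marks fungi; monounsaturated and cyclopropyl acids mark
gram-negative bacteria; iso/anteiso branched acids mark gram-positive
bacteria; 10-methyl branched acids mark actinomycetes; 20:4 marks
micro-fauna.  The default catalog carries 24 biomarkers, of which 14 are
group-assigned; the rest contribute to total biomass only.
"""

from __future__ import annotations

import re
from importlib import resources
from typing import Mapping, NamedTuple, Optional

import numpy as np
import pandas as pd

from .errors import (
    EmptyInputError,
    InvalidBiomarkerError,
    InvalidMeasurementError,
    MissingReferenceError,
    UndefinedRatioError,
)
from .isotope import DEFAULT_CONSTANTS, IsotopeConstants, excess_13c_mass

GROUPS = ("fungi", "gram_negative", "gram_positive", "actinomycetes", "microfauna")
GROUP_LABELS = GROUPS + ("unassigned",)
#: Pseudo-group meaning "all catalogued biomarkers".
TOTAL = "total"

_NAME_RE = re.compile(
    r"^(?P<me>10Me)?(?:cy|i|a)?(?P<length>\d+):\d+(?:ω\d+|w\d+)?$"
)


def parse_n_carbons(biomarker: str) -> int:
    """Carbon count of the underivatized fatty acid, parsed from its name.

    The acyl chain length is the leading number of the shorthand
    (18:2w6 -> 18); a 10-methyl branch adds one carbon (10Me16:0 -> 17).
    Raises InvalidBiomarkerError when the name cannot be parsed — such
    biomarkers need an explicit catalog entry.
    """
    m = _NAME_RE.match(biomarker.strip())
    if m is None:
        raise InvalidBiomarkerError(
            f"cannot parse carbon count from biomarker name {biomarker!r}"
        )
    return int(m.group("length")) + (1 if m.group("me") else 0)


def load_catalog(path=None) -> pd.DataFrame:
    """Load a biomarker catalog (TSV: biomarker, group, n_carbons).

    With no path, loads the package default (24 biomarkers).  The returned
    frame is indexed by biomarker name.
    """
    if path is None:
        src = resources.files("plfasip.data").joinpath("catalog.tsv")
        with src.open("r", encoding="utf-8") as fh:
            cat = pd.read_csv(fh, sep="\t", comment="#")
    else:
        cat = pd.read_csv(path, sep="\t", comment="#")
    required = {"biomarker", "group", "n_carbons"}
    if not required.issubset(cat.columns):
        raise InvalidBiomarkerError(
            f"catalog must have columns {sorted(required)}, got {list(cat.columns)}"
        )
    if cat["biomarker"].duplicated().any():
        dups = cat.loc[cat["biomarker"].duplicated(), "biomarker"].tolist()
        raise InvalidBiomarkerError(f"duplicate catalog biomarkers: {dups}")
    bad_groups = set(cat["group"]) - set(GROUP_LABELS)
    if bad_groups:
        raise InvalidBiomarkerError(f"unknown group labels in catalog: {sorted(bad_groups)}")
    if (cat["n_carbons"] < 1).any():
        raise InvalidBiomarkerError("catalog n_carbons must be >= 1")
    return cat.set_index("biomarker")


def members(catalog: pd.DataFrame, group: str) -> list[str]:
    """Biomarkers belonging to ``group`` (or all of them for ``total``)."""
    if group == TOTAL:
        return list(catalog.index)
    if group not in GROUP_LABELS:
        raise InvalidBiomarkerError(f"unknown group {group!r}")
    return list(catalog.index[catalog["group"] == group])


def assign_groups(biomarkers: pd.Series, catalog: pd.DataFrame) -> tuple[pd.Series, list[str]]:
    """Map biomarker names to group labels.

    Names absent from the catalog are routed to ``unassigned`` and returned
    in the warning list (they still count toward total biomass).
    """
    mapped = biomarkers.map(catalog["group"])
    unknown = sorted(set(biomarkers[mapped.isna()]))
    return mapped.fillna("unassigned"), unknown


class GroupTotals(NamedTuple):
    biomass: float  # nmol C g^-1 dry soil
    excess_13c: Optional[float]  # nmol 13C g^-1 dry soil; None if no control given
    excess_flagged: bool  # any negative per-biomarker excess


def aggregate_group(
    measurements: pd.DataFrame,
    catalog: pd.DataFrame,
    group: str,
    control_deltas: Optional[Mapping[str, float]] = None,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> GroupTotals:
    """Sum biomass (and, given matched controls, excess 13C) over a group.

    ``measurements`` needs columns ``biomarker``, ``amount`` (nmol C g^-1)
    and, for the excess, ``delta`` (the FAME-corrected delta13C).
    ``control_deltas`` maps each biomarker to the corrected delta13C of the
    time-matched no-litter control; a member biomarker missing from it raises
    MissingReferenceError.
    """
    sel = members(catalog, group)
    sub = measurements[measurements["biomarker"].isin(sel)]
    biomass = float(sub["amount"].sum())
    if control_deltas is None:
        return GroupTotals(biomass, None, False)
    missing = sorted(set(sub["biomarker"]) - set(control_deltas))
    if missing:
        raise MissingReferenceError(
            f"no matched no-litter control delta for biomarkers {missing}"
        )
    flagged = False
    excess = 0.0
    for _, row in sub.iterrows():
        ex = excess_13c_mass(
            row["delta"], control_deltas[row["biomarker"]], row["amount"], constants
        )
        excess += ex.value
        flagged |= ex.flagged
    return GroupTotals(biomass, excess, flagged)


class CommunityRatios(NamedTuple):
    fungal_bacterial: Optional[float]
    gram_pos_neg: Optional[float]


def community_ratios(
    biomass_by_group: Mapping[str, float],
    include_actinomycetes: bool = False,
) -> CommunityRatios:
    """Fungal/bacterial and G+/G- biomass ratios for one sample.

    "Bacterial" is gram_negative + gram_positive by default; actinomycetes
    (filamentous gram-positives) can be folded in with the flag.  A zero
    denominator yields None for that ratio (undefined, flagged by absence)
    rather than an exception when the other ratio is still computable; asking
    for a ratio from an all-zero community raises.
    """
    fungi = float(biomass_by_group.get("fungi", 0.0))
    gn = float(biomass_by_group.get("gram_negative", 0.0))
    gp = float(biomass_by_group.get("gram_positive", 0.0))
    bacterial = gn + gp + (
        float(biomass_by_group.get("actinomycetes", 0.0)) if include_actinomycetes else 0.0
    )
    if bacterial <= 0 and gn <= 0:
        raise UndefinedRatioError("no bacterial biomass: both ratios undefined")
    fb = fungi / bacterial if bacterial > 0 else None
    gpgn = gp / gn if gn > 0 else None
    return CommunityRatios(fb, gpgn)


def mean_community_ratios(
    per_sample: pd.DataFrame,
    include_actinomycetes: bool = False,
    method: str = "mean_of_ratios",
) -> CommunityRatios:
    """Average community ratios over replicate samples.

    ``per_sample`` is long-format with columns sample_id, group, biomass.
    ``mean_of_ratios`` (default) computes the ratio per replicate and then
    averages; ``ratio_of_means`` averages the biomass first.
    """
    wide = per_sample.pivot_table(
        index="sample_id", columns="group", values="biomass", aggfunc="sum"
    ).fillna(0.0)
    if method == "ratio_of_means":
        return community_ratios(wide.mean(axis=0).to_dict(), include_actinomycetes)
    if method != "mean_of_ratios":
        raise ValueError(f"unknown method {method!r}")
    ratios = [
        community_ratios(row.to_dict(), include_actinomycetes)
        for _, row in wide.iterrows()
    ]
    fb = [r.fungal_bacterial for r in ratios if r.fungal_bacterial is not None]
    gpgn = [r.gram_pos_neg for r in ratios if r.gram_pos_neg is not None]
    return CommunityRatios(
        float(np.mean(fb)) if fb else None,
        float(np.mean(gpgn)) if gpgn else None,
    )


def relative_abundance(amounts: pd.Series) -> pd.Series:
    """Per-biomarker mol C percent of one sample's total PLFA.

    ``amounts`` is indexed by biomarker; the result sums to 100 exactly.
    """
    if len(amounts) == 0:
        raise EmptyInputError("empty sample")
    total = float(amounts.sum())
    if total <= 0:
        raise InvalidMeasurementError("all-zero sample: relative abundance undefined")
    return amounts / total * 100.0


def relative_abundance_table(measurements: pd.DataFrame) -> pd.DataFrame:
    """Add a ``rel_abundance_pct`` column, normalizing within each sample_id."""
    totals = measurements.groupby("sample_id")["amount"].transform("sum")
    if (totals <= 0).any():
        bad = sorted(measurements.loc[totals <= 0, "sample_id"].unique())
        raise InvalidMeasurementError(f"all-zero samples: {bad}")
    out = measurements.copy()
    out["rel_abundance_pct"] = out["amount"] / totals * 100.0
    return out


def total_mineral_n(no3_n, nh4_n):
    """Total mineral nitrogen as the sum of nitrate-N and ammonium-N (nmol g^-1)."""
    no3 = np.asarray(no3_n, dtype=float)
    nh4 = np.asarray(nh4_n, dtype=float)
    if np.any(no3 < 0) or np.any(nh4 < 0):
        raise InvalidMeasurementError("mineral N inputs must be >= 0")
    out = no3 + nh4
    return out if out.ndim else float(out)
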