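"""Stable-isotope arithmetic for compound-specific 13C analysis.

All deltas are per-mil (permil) deviations of the 13C/12C ratio from the
VPDB standard.  Atom fraction, 13C/(12C + 13C), is the currency for any
mass-balance step; delta notation is kept for the mixing model, which the
underlying two-pool partitioning uses in its delta-linear form.

Functions accept scalars or numpy arrays and broadcast accordingly.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

from .errors import (
    DegenerateEndmemberError,
    InvalidBiomarkerError,
    InvalidIsotopeValueError,
    InvalidMeasurementError,
)

#: 13C/12C ratio of the VPDB standard. Configurable via IsotopeConstants;
#: every pipeline run echoes the value actually used into its metadata.
R_VPDB_DEFAULT = 0.0111802

#: The delta value corresponding to an atom fraction of exactly zero.
DELTA_ZERO_13C = -1000.0


@dataclass(frozen=True)
class IsotopeConstants:
    """Fixed isotope-standard constants for one pipeline run."""

    r_vpdb: float = R_VPDB_DEFAULT

    def __post_init__(self) -> None:
        if not self.r_vpdb > 0:
            raise InvalidIsotopeValueError(
                f"r_vpdb must be positive, got {self.r_vpdb}"
            )


DEFAULT_CONSTANTS = IsotopeConstants()


@dataclass(frozen=True)
class MixingEndmembers:
    """The two carbon sources of the mixing model.

    delta_litter : permil
        delta13C of the added litter (the labeled substrate).
    delta_soil : permil
        delta13C of the bulk native soil carbon at experiment start.
    """

    delta_litter: float
    delta_soil: float

    def __post_init__(self) -> None:
        validate_delta(self.delta_litter)
        validate_delta(self.delta_soil)
        if self.delta_litter == self.delta_soil:
            raise DegenerateEndmemberError(
                "litter and soil endmembers coincide "
                f"({self.delta_litter} permil): mixing model is undefined"
            )


class Flagged(NamedTuple):
    """A value carrying a quality flag (never clipped, never silently fixed)."""

    value: float
    flagged: bool

    def __float__(self) -> float:  # pragma: no cover - convenience
        return float(self.value)


def validate_delta(delta) -> None:
    """Reject deltas at or below -1000 permil (atom fraction <= 0)."""
    if np.any(np.asarray(delta) < DELTA_ZERO_13C) or not np.all(
        np.isfinite(np.asarray(delta, dtype=float))
    ):
        raise InvalidIsotopeValueError(
            f"delta13C must be finite and >= {DELTA_ZERO_13C} permil, got {delta}"
        )


#: Endmembers of the default litter-amendment scenario: 13C-labeled litter at
#: 904.0 permil, native soil carbon at -25.7 permil.
DEFAULT_ENDMEMBERS = MixingEndmembers(delta_litter=904.0, delta_soil=-25.7)


def delta_to_atom_fraction(delta, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Convert delta13C (permil vs VPDB) to atom fraction 13C.

    AF = R / (1 + R) with R = r_vpdb * (delta/1000 + 1).  Strictly
    increasing in delta; AF(-1000) = 0.
    """
    validate_delta(delta)
    r = constants.r_vpdb * (np.asarray(delta, dtype=float) / 1000.0 + 1.0)
    af = r / (1.0 + r)
    return af if af.ndim else float(af)


def atom_fraction_to_delta(af, constants: IsotopeConstants = DEFAULT_CONSTANTS):
    """Exact inverse of :func:`delta_to_atom_fraction`; af must lie in [0, 1)."""
    af_arr = np.asarray(af, dtype=float)
    if np.any(af_arr < 0) or np.any(af_arr >= 1) or not np.all(np.isfinite(af_arr)):
        raise InvalidIsotopeValueError(
            f"atom fraction must lie in [0, 1), got {af}"
        )
    r = af_arr / (1.0 - af_arr)
    delta = (r / constants.r_vpdb - 1.0) * 1000.0
    return delta if delta.ndim else float(delta)


def correct_fame_delta(delta_fame, delta_methanol, n_carbons):
    """Remove the methanol-derived carbon from a FAME delta13C.

    PLFAs are measured as fatty-acid methyl esters; the methylation adds one
    carbon from the derivatization methanol.  With n the number of carbon
    atoms in the underivatized PLFA,

        delta_PLFA = ((n + 1) * delta_FAME - delta_methanol) / n.
    """
    n = np.asarray(n_carbons)
    if np.any(n < 1) or not np.issubdtype(n.dtype, np.number):
        raise InvalidBiomarkerError(f"n_carbons must be >= 1, got {n_carbons}")
    validate_delta(delta_fame)
    validate_delta(delta_methanol)
    n = np.asarray(n_carbons, dtype=float)
    out = ((n + 1.0) * np.asarray(delta_fame, dtype=float)
           - np.asarray(delta_methanol, dtype=float)) / n
    return out if out.ndim else float(out)


def fame_forward_delta(delta_plfa, delta_methanol, n_carbons):
    """Forward derivatization model: the FAME delta implied by a PLFA delta.

    delta_FAME = (n * delta_PLFA + delta_methanol) / (n + 1); the exact
    mass-balance inverse of :func:`correct_fame_delta`.  Used by the
    synthetic-data generator so the analysis must undo the derivatization.
    """
    n = np.asarray(n_carbons, dtype=float)
    if np.any(n < 1):
        raise InvalidBiomarkerError(f"n_carbons must be >= 1, got {n_carbons}")
    out = (n * np.asarray(delta_plfa, dtype=float)
           + np.asarray(delta_methanol, dtype=float)) / (n + 1.0)
    return out if out.ndim else float(out)


def excess_13c_mass(
    delta_labeled,
    delta_control,
    carbon_amount,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> Flagged:
    """Excess 13C (nmol 13C) in a carbon pool relative to an unlabeled control.

    excess = (AF(delta_labeled) - AF(delta_control)) * carbon_amount.

    Measurement noise can make the excess negative; the value is returned
    as-is with ``flagged=True`` rather than clipped, because clipping would
    bias any downstream aggregate.
    """
    amount = np.asarray(carbon_amount, dtype=float)
    if np.any(amount < 0):
        raise InvalidMeasurementError(
            f"carbon_amount must be >= 0, got {carbon_amount}"
        )
    af_l = delta_to_atom_fraction(delta_labeled, constants)
    af_c = delta_to_atom_fraction(delta_control, constants)
    value = (np.asarray(af_l) - np.asarray(af_c)) * amount
    if value.ndim:
        return Flagged(value, bool(np.any(value < 0)))
    return Flagged(float(value), bool(value < 0))


def fraction_litter_derived(
    delta_sample,
    delta_reference,
    endmembers: MixingEndmembers = DEFAULT_ENDMEMBERS,
) -> Flagged:
    """Percent of a carbon pool derived from the added litter (two-pool model).

    %C_litter = 100 * (delta_sample - delta_reference)
                     / (delta_litter - delta_soil)

    where delta_reference is the time-matched sample without litter addition.
    Noise can push values slightly outside [0, 100]; such values are returned
    unmodified with ``flagged=True``.
    """
    validate_delta(delta_sample)
    validate_delta(delta_reference)
    span = endmembers.delta_litter - endmembers.delta_soil
    pct = 100.0 * (
        np.asarray(delta_sample, dtype=float)
        - np.asarray(delta_reference, dtype=float)
    ) / span
    out_of_range = (pct < 0) | (pct > 100)
    if pct.ndim:
        return Flagged(pct, bool(np.any(out_of_range)))
    return Flagged(float(pct), bool(out_of_range))


def mix_delta(fraction_litter, endmembers: MixingEndmembers = DEFAULT_ENDMEMBERS):
    """Delta of a pool that is ``fraction_litter`` litter-derived (0-1 scale).

    The delta-linear forward model inverted by
    :func:`fraction_litter_derived` when the reference sits at the soil
    endmember.
    """
    f = np.asarray(fraction_litter, dtype=float)
    out = f * endmembers.delta_litter + (1.0 - f) * endmembers.delta_soil
    return out if out.ndim else float(out)


def fraction_litter_derived_atom_fraction(
    delta_sample,
    delta_reference,
    endmembers: MixingEndmembers = DEFAULT_ENDMEMBERS,
    constants: IsotopeConstants = DEFAULT_CONSTANTS,
) -> Flagged:
    """Atom-fraction-based variant of the two-pool model, for sensitivity checks.

    Partitions in atom-fraction space (exact isotope mass balance) instead of
    the delta-linear form.  Off by default throughout the pipeline because the
    delta-linear form is the model as conventionally applied.
    """
    af_s = np.asarray(delta_to_atom_fraction(delta_sample, constants))
    af_r = np.asarray(delta_to_atom_fraction(delta_reference, constants))
    af_l = delta_to_atom_fraction(endmembers.delta_litter, constants)
    af_soil = delta_to_atom_fraction(endmembers.delta_soil, constants)
    pct = 100.0 * (af_s - af_r) / (af_l - af_soil)
    out_of_range = (pct < 0) | (pct > 100)
    if pct.ndim:
        return Flagged(pct, bool(np.any(out_of_range)))
    return Flagged(float(pct), bool(out_of_range))
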