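"""Subcellular localization and polysome-gradient translation evidence.

Cytoplasmic export is quantified as ``fpkm_cyt / (fpkm_cyt + fpkm_nuc)`` from
compartment RNA-seq; a transcript is called exported when this fraction
reaches a configurable floor (default 0.2 — a deliberately low bar, since a
transcript only needs clear cytoplasmic presence, not cytoplasmic dominance,
to be translatable).

Sucrose-gradient qPCR CT values are turned into a per-fraction RNA
distribution by inverting exponential amplification: with per-cycle
efficiency E, template abundance is proportional to E^(-CT), so

    p_i = E^(-ct_i) / sum_j E^(-ct_j)

Missing CT (no amplification) contributes zero mass.  The polysome score is
the summed mass over the fractions designated polysomal (by default the
bottom 40% of the gradient, where the heavy, multi-ribosome material
sediments); a transcript is called translated when that score reaches the
translation cutoff (default 0.5).  Reference normalization uses the same
exponential model: relative level = E^(-(CT_target - CT_reference)).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LocalizationCall",
    "FractionProfile",
    "cytoplasmic_fraction",
    "call_localization",
    "fraction_distribution",
    "polysome_enrichment",
    "relative_expression",
    "default_polysome_set",
    "profiles_from_ct_table",
]

DEFAULT_EXPORT_THRESHOLD = 0.2
DEFAULT_TRANSLATION_CUTOFF = 0.5
DEFAULT_EFFICIENCY = 2.0
DEFAULT_BOTTOM_FRACTION = 0.4


@dataclass(frozen=True)
class LocalizationCall:
    """Nuclear/cytoplasmic export verdict for one transcript."""

    transcript_id: str
    cytoplasmic_fraction: float
    exported: bool

    def __post_init__(self) -> None:
        if not 0.0 <= self.cytoplasmic_fraction <= 1.0:
            raise ValueError("cytoplasmic_fraction must lie in [0, 1]")


def cytoplasmic_fraction(fpkm_cyt: float, fpkm_nuc: float) -> float:
    """Fraction of a transcript's signal found in the cytoplasm."""
    if fpkm_cyt < 0 or fpkm_nuc < 0:
        raise ValueError("compartment FPKMs must be non-negative")
    if fpkm_cyt == 0 and fpkm_nuc == 0:
        raise ValueError("transcript not expressed in either compartment")
    return fpkm_cyt / (fpkm_cyt + fpkm_nuc)


def call_localization(
    transcript_id: str,
    fpkm_cyt: float,
    fpkm_nuc: float,
    export_threshold: float = DEFAULT_EXPORT_THRESHOLD,
) -> LocalizationCall:
    frac = cytoplasmic_fraction(fpkm_cyt, fpkm_nuc)
    return LocalizationCall(transcript_id, frac, frac >= export_threshold)


def _check_efficiency(efficiency: float) -> None:
    if not 1.0 < efficiency <= 2.0:
        raise ValueError(
            f"amplification efficiency must lie in (1, 2], got {efficiency}"
        )


def fraction_distribution(
    ct_values: Sequence[float], efficiency: float = DEFAULT_EFFICIENCY
) -> np.ndarray:
    """Per-fraction RNA mass implied by CT values (NaN = no amplification = 0).

    Normalized so present fractions sum to 1; invariant under adding a
    constant to every CT (only relative cycle differences carry information).
    """
    _check_efficiency(efficiency)
    ct = np.asarray(ct_values, dtype=float)
    present = ~np.isnan(ct)
    if not present.any():
        raise ValueError("all CT values absent")
    weights = np.zeros_like(ct)
    # subtract the min CT before exponentiating so large CTs cannot underflow
    weights[present] = efficiency ** -(ct[present] - ct[present].min())
    return weights / weights.sum()


@dataclass(frozen=True)
class FractionProfile:
    """One transcript's ordered gradient fractions, CTs and derived distribution."""

    transcript_id: str
    fraction_labels: tuple[str, ...]
    ct_values: tuple[float, ...]  # NaN = no amplification
    polysome_set: frozenset[int]
    efficiency: float = DEFAULT_EFFICIENCY
    distribution: tuple[float, ...] = field(init=False)

    def __post_init__(self) -> None:
        if len(self.fraction_labels) != len(self.ct_values):
            raise ValueError("one CT per fraction label required")
        indices = set(range(len(self.fraction_labels)))
        if not set(self.polysome_set) <= indices:
            raise ValueError("polysome_set must be a subset of fraction indices")
        dist = fraction_distribution(self.ct_values, self.efficiency)
        object.__setattr__(self, "distribution", tuple(float(p) for p in dist))


def polysome_enrichment(
    profile: FractionProfile,
    translation_cutoff: float = DEFAULT_TRANSLATION_CUTOFF,
) -> tuple[float, bool]:
    """Summed RNA mass in the polysomal fractions, and the translated call."""
    if not profile.polysome_set:
        raise ValueError("polysome_set must not be empty")
    score = float(sum(profile.distribution[i] for i in profile.polysome_set))
    return score, score >= translation_cutoff


def relative_expression(
    ct_target: float, ct_reference: float, efficiency: float = DEFAULT_EFFICIENCY
) -> float:
    """Delta-Ct relative level: efficiency^(-(CT_target - CT_reference))."""
    _check_efficiency(efficiency)
    if ct_target is None or ct_reference is None or math.isnan(ct_target) or math.isnan(ct_reference):
        raise ValueError("both CT values must be present")
    return float(efficiency ** -(ct_target - ct_reference))


def default_polysome_set(
    n_fractions: int, bottom_fraction: float = DEFAULT_BOTTOM_FRACTION
) -> frozenset[int]:
    """Indices of the bottom ``bottom_fraction`` of an n-fraction gradient.

    Fractions are ordered top (light) to bottom (heavy); the heavy bottom of
    the gradient is where polysome-bound RNA sediments.
    """
    if n_fractions < 1:
        raise ValueError("n_fractions must be positive")
    if not 0.0 < bottom_fraction <= 1.0:
        raise ValueError("bottom_fraction must lie in (0, 1]")
    n_polysomal = math.ceil(bottom_fraction * n_fractions)
    return frozenset(range(n_fractions - n_polysomal, n_fractions))


def profiles_from_ct_table(
    table: pd.DataFrame,
    polysome_set: frozenset[int] | None = None,
    efficiency: float = DEFAULT_EFFICIENCY,
    bottom_fraction: float = DEFAULT_BOTTOM_FRACTION,
) -> dict[str, FractionProfile]:
    """Build one :class:`FractionProfile` per row of a CT table.

    Rows that never amplified (all NaN) are skipped.
    """
    if polysome_set is None:
        polysome_set = default_polysome_set(table.shape[1], bottom_fraction)
    labels = tuple(str(c) for c in table.columns)
    profiles: dict[str, FractionProfile] = {}
    for tid, row in table.iterrows():
        ct = tuple(float(v) for v in row.to_numpy())
        if all(math.isnan(v) for v in ct):
            continue
        profiles[str(tid)] = FractionProfile(
            transcript_id=str(tid),
            fraction_labels=labels,
            ct_values=ct,
            polysome_set=polysome_set,
            efficiency=efficiency,
        )
    return profiles
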