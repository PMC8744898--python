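"""Tumor-exclusive expression filtering.

A transcript is called *exclusive* when it is expressed in the tumor sample
(FPKM >= tau_on) and silent in every normal sample (FPKM <= tau_off).  FPKM
between the two thresholds is *ambiguous* and conservatively disqualifies a
candidate: low-level normal expression is evidence against tumor specificity.

Defaults are tau_on = 1.0 and tau_off = 0.0 FPKM — a conventional 1-FPKM
expression floor and a strict zero for silence, matching screens in which the
retained candidates show exactly zero normal-tissue signal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from .io_formats import ExpressionMatrix

__all__ = [
    "ScreenThresholds",
    "ExclusivityCall",
    "classify_expression",
    "find_exclusive_transcripts",
    "confirm_in_replicate",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ScreenThresholds:
    """FPKM cutoffs for "expressed" (tau_on) and "not expressed" (tau_off)."""

    tau_on: float = 1.0
    tau_off: float = 0.0

    def __post_init__(self) -> None:
        if self.tau_off < 0:
            raise ValueError(f"tau_off must be >= 0, got {self.tau_off}")
        if self.tau_on <= self.tau_off:
            raise ValueError(
                f"tau_on ({self.tau_on}) must exceed tau_off ({self.tau_off})"
            )


@dataclass(frozen=True)
class ExclusivityCall:
    """Per-transcript verdict of the exclusivity screen."""

    transcript_id: str
    tumor_fpkm: float
    max_normal_fpkm: float
    status: str  # exclusive | shared | silent

    def __post_init__(self) -> None:
        if self.status not in ("exclusive", "shared", "silent"):
            raise ValueError(f"unknown status {self.status!r}")


def classify_expression(fpkm: float, thresholds: ScreenThresholds) -> str:
    """Classify one FPKM value as ``on``, ``off`` or ``ambiguous``."""
    if fpkm < 0:
        raise ValueError(f"FPKM must be non-negative, got {fpkm}")
    if fpkm >= thresholds.tau_on:
        return "on"
    if fpkm <= thresholds.tau_off:
        return "off"
    return "ambiguous"


def _check_samples(matrix: ExpressionMatrix, samples: Iterable[str]) -> None:
    known = set(matrix.sample_ids)
    for sample in samples:
        if sample not in known:
            raise KeyError(f"sample {sample!r} not present in matrix")


def find_exclusive_transcripts(
    matrix: ExpressionMatrix,
    tumor_sample: str,
    normal_samples: Sequence[str],
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[ExclusivityCall]:
    """Return transcripts on in the tumor and off in *every* normal sample.

    Ambiguous expression (between tau_off and tau_on) in any normal sample
    disqualifies a transcript.  Output is sorted by descending tumor FPKM,
    ties broken by transcript id.
    """
    normal_samples = list(normal_samples)
    if not normal_samples:
        raise ValueError("normal_samples must not be empty")
    _check_samples(matrix, [tumor_sample, *normal_samples])

    tumor = matrix.values[tumor_sample]
    normals = matrix.values[normal_samples]
    on_in_tumor = tumor >= thresholds.tau_on
    off_in_all_normals = (normals <= thresholds.tau_off).all(axis=1)
    keep = on_in_tumor & off_in_all_normals

    calls = [
        ExclusivityCall(
            transcript_id=str(tid),
            tumor_fpkm=float(tumor.at[tid]),
            max_normal_fpkm=float(normals.loc[tid].max()),
            status="exclusive",
        )
        for tid in matrix.values.index[keep]
    ]
    calls.sort(key=lambda c: (-c.tumor_fpkm, c.transcript_id))
    return calls


def confirm_in_replicate(
    calls: Sequence[ExclusivityCall],
    replicate: ExpressionMatrix,
    tumor_sample: str,
    thresholds: ScreenThresholds = ScreenThresholds(),
) -> list[ExclusivityCall]:
    """Keep only calls whose transcript is also on in an independent tumor dataset.

    Transcripts absent from the replicate matrix are dropped and reported via
    logging, as are transcripts that fail the replicate expression floor.
    """
    _check_samples(replicate, [tumor_sample])
    kept: list[ExclusivityCall] = []
    for call in calls:
        if call.transcript_id not in replicate.values.index:
            logger.info(
                "confirm_in_replicate: %s absent from replicate matrix, dropped",
                call.transcript_id,
            )
            continue
        level = replicate.value(call.transcript_id, tumor_sample)
        if classify_expression(level, thresholds) == "on":
            kept.append(call)
        else:
            logger.info(
                "confirm_in_replicate: %s not expressed in replicate (%.3f FPKM), dropped",
                call.transcript_id,
                level,
            )
    return kept
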