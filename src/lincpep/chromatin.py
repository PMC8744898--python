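"""Promoter chromatin-accessibility annotation.

Each candidate's putative proximal promoter (default 1000 bp upstream to
500 bp downstream of the TSS, strand-aware) is intersected with tumor and
normal DNase-hypersensitivity peak tracks, arbitrary named feature tracks
(cCREs, histone-mark or TF ChIP peaks), and CAGE TSS clusters.  A promoter is
*differentially open* when it holds at least one tumor DNase peak and no
normal DNase peak.  Accessibility is annotated evidence, never a hard filter:
candidates lacking open chromatin stay in the screen.

Overlap counting uses >= 1 shared base under half-open semantics and ignores
strand (DNase is unstranded); intervals on other chromosomes contribute zero.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

from intervaltree import IntervalTree

from .io_formats import GenomicInterval, TranscriptModel

__all__ = [
    "PromoterAnnotation",
    "promoter_window",
    "count_overlaps",
    "annotate_promoter",
]

DEFAULT_UPSTREAM = 1000
DEFAULT_DOWNSTREAM = 500
DEFAULT_CAGE_SLACK = 100


@dataclass(frozen=True)
class PromoterAnnotation:
    """Chromatin evidence accumulated over one candidate promoter window."""

    transcript_id: str
    window: GenomicInterval
    tumor_dnase_peaks: int
    normal_dnase_peaks: int
    differential_open: bool
    feature_counts: Mapping[str, int] = field(default_factory=dict)
    cage_supported: bool = False

    def __post_init__(self) -> None:
        if self.tumor_dnase_peaks < 0 or self.normal_dnase_peaks < 0:
            raise ValueError("peak counts must be non-negative")
        if any(count < 0 for count in self.feature_counts.values()):
            raise ValueError("feature counts must be non-negative")
        expected = self.tumor_dnase_peaks >= 1 and self.normal_dnase_peaks == 0
        if self.differential_open != expected:
            raise ValueError(
                "differential_open must hold iff >=1 tumor peak and 0 normal peaks"
            )


def promoter_window(
    transcript: TranscriptModel,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> GenomicInterval:
    """Strand-aware promoter window around the TSS, clipped at position 0.

    Plus strand: ``[tss - upstream, tss + downstream)``; minus strand the
    mirror image ``[tss - downstream + 1, tss + upstream + 1)``, so the window
    always covers ``upstream`` bases 5' and ``downstream`` bases 3' of the TSS
    in transcript orientation.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("upstream and downstream must be >= 0")
    if upstream == 0 and downstream == 0:
        raise ValueError("promoter window cannot be empty")
    if transcript.strand == "+":
        start, end = transcript.tss - upstream, transcript.tss + downstream
    else:
        start, end = transcript.tss - downstream + 1, transcript.tss + upstream + 1
    start = max(0, start)
    if end <= start:
        raise ValueError(
            f"promoter window of {transcript.id!r} is empty after clipping at 0"
        )
    return GenomicInterval(
        transcript.chrom, start, end, ".", f"{transcript.id}_promoter"
    )


def count_overlaps(
    window: GenomicInterval, track: Sequence[GenomicInterval]
) -> int:
    """Count track intervals sharing >= 1 base with ``window`` (strand ignored)."""
    tree = IntervalTree()
    for i, iv in enumerate(track):
        if iv.chrom == window.chrom:
            # distinct payloads keep duplicate coordinates as separate peaks
            tree.addi(iv.start, iv.end, i)
    return len(tree.overlap(window.start, window.end))


def annotate_promoter(
    transcript: TranscriptModel,
    tumor_dnase: Sequence[GenomicInterval],
    normal_dnase: Sequence[GenomicInterval],
    feature_tracks: Mapping[str, Sequence[GenomicInterval]] | None = None,
    cage: Sequence[GenomicInterval] | None = None,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
    cage_slack: int = DEFAULT_CAGE_SLACK,
) -> PromoterAnnotation:
    """Assemble all chromatin evidence for one transcript's promoter.

    ``cage_supported`` is true when at least one CAGE cluster lies within
    ``cage_slack`` bp of the annotated TSS (the capped 5' end should coincide
    with the transcription start).
    """
    window = promoter_window(transcript, upstream, downstream)
    tumor_peaks = count_overlaps(window, tumor_dnase)
    normal_peaks = count_overlaps(window, normal_dnase)
    feature_counts = {
        name: count_overlaps(window, trk)
        for name, trk in (feature_tracks or {}).items()
    }
    cage_supported = False
    if cage:
        cage_window = GenomicInterval(
            transcript.chrom,
            max(0, transcript.tss - cage_slack),
            transcript.tss + cage_slack + 1,
        )
        cage_supported = count_overlaps(cage_window, cage) >= 1
    return PromoterAnnotation(
        transcript_id=transcript.id,
        window=window,
        tumor_dnase_peaks=tumor_peaks,
        normal_dnase_peaks=normal_peaks,
        differential_open=tumor_peaks >= 1 and normal_peaks == 0,
        feature_counts=feature_counts,
        cage_supported=cage_supported,
    )
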