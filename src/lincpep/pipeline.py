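"""End-to-end screen orchestration: funnel, evidence records and reports.

Stages run in a fixed order — exclusivity, replicate confirmation, ORF
filter, cytoplasmic export, polysome translation — each consuming the
survivors of the previous one.  Promoter chromatin annotation is computed for
every confirmed candidate but is *evidence only*: a closed promoter never
removes a candidate.  A stage whose inputs are not configured is skipped and
recorded as not evaluated, freezing its survivors at the previous stage.

The funnel summary counts survivors per stage; counts are non-increasing by
construction.  Reports are written as machine JSON (schema-versioned and
round-trippable), a per-transcript evidence TSV, and a plain-text funnel.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import chromatin, polysome
from .chromatin import PromoterAnnotation
from .expression_screen import (
    ExclusivityCall,
    ScreenThresholds,
    confirm_in_replicate,
    find_exclusive_transcripts,
)
from .io_formats import (
    ExpressionMatrix,
    GenomicInterval,
    TranscriptModel,
    read_bed,
    read_ct_table,
    read_expression_table,
    read_fasta,
    read_sample_metadata,
    read_transcript_models,
)
from .orf_scan import OpenReadingFrame, find_orfs
from .polysome import LocalizationCall, call_localization, polysome_enrichment

__all__ = [
    "STAGES",
    "CandidateRecord",
    "PipelineConfig",
    "screen_cohort",
    "run_screen",
    "write_report",
    "read_report",
]

STAGES = ("exclusive", "confirmed", "has_orf", "exported", "translated")
REPORT_SCHEMA_VERSION = "1"


@dataclass
class CandidateRecord:
    """Accumulated per-transcript evidence and the furthest stage passed."""

    transcript_id: str
    exclusivity: ExclusivityCall
    stage_reached: str
    promoter: PromoterAnnotation | None = None
    orfs: tuple[OpenReadingFrame, ...] = ()
    localization: LocalizationCall | None = None
    translation_score: float | None = None
    translated: bool | None = None
    final_candidate: bool = False
    drop_reason: str | None = None

    def __post_init__(self) -> None:
        if self.stage_reached not in STAGES:
            raise ValueError(f"unknown stage {self.stage_reached!r}")
        if self.final_candidate != (self.stage_reached == "translated"):
            raise ValueError("final_candidate must hold iff stage_reached is translated")


@dataclass
class PipelineConfig:
    """One structured configuration drives a full run."""

    # stage parameters
    tau_on: float = 1.0
    tau_off: float = 0.0
    tumor_sample: str | None = None  # None -> resolved by sample role
    normal_samples: tuple[str, ...] | None = None
    upstream: int = chromatin.DEFAULT_UPSTREAM
    downstream: int = chromatin.DEFAULT_DOWNSTREAM
    cage_slack: int = chromatin.DEFAULT_CAGE_SLACK
    min_len_aa: int = 50
    export_threshold: float = polysome.DEFAULT_EXPORT_THRESHOLD
    translation_cutoff: float = polysome.DEFAULT_TRANSLATION_CUTOFF
    efficiency: float = polysome.DEFAULT_EFFICIENCY
    polysome_bottom_fraction: float = polysome.DEFAULT_BOTTOM_FRACTION
    seed: int = 0
    # input paths (relative to base_dir of the config file)
    expression: str | None = None
    samples: str | None = None
    replicate: str | None = None
    replicate_samples: str | None = None
    sequences: str | None = None
    transcript_models: str | None = None
    tumor_dnase: str | None = None
    normal_dnase: str | None = None
    cage: str | None = None
    feature_tracks: dict[str, str] = field(default_factory=dict)
    ct_table: str | None = None
    output_dir: str = "results"

    @property
    def thresholds(self) -> ScreenThresholds:
        return ScreenThresholds(tau_on=self.tau_on, tau_off=self.tau_off)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as handle:
            raw = yaml.safe_load(handle) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "normal_samples" in raw and raw["normal_samples"] is not None:
            raw["normal_samples"] = tuple(raw["normal_samples"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        if data["normal_samples"] is not None:
            data["normal_samples"] = list(data["normal_samples"])
        with Path(path).open("w") as handle:
            yaml.safe_dump(data, handle, sort_keys=False)


def _resolve_sample(matrix: ExpressionMatrix, role: str, configured: str | None) -> str:
    if configured is not None:
        if configured not in matrix.sample_ids:
            raise KeyError(f"sample {configured!r} not present in matrix")
        return configured
    candidates = matrix.samples_with_role(role)
    if len(candidates) != 1:
        raise ValueError(
            f"expected exactly one sample with role {role!r}, found {candidates}"
        )
    return candidates[0]


def screen_cohort(
    matrix: ExpressionMatrix,
    *,
    replicate: ExpressionMatrix | None = None,
    sequences: Mapping[str, str] | None = None,
    models: Mapping[str, TranscriptModel] | None = None,
    tumor_dnase: Sequence[GenomicInterval] | None = None,
    normal_dnase: Sequence[GenomicInterval] | None = None,
    feature_tracks: Mapping[str, Sequence[GenomicInterval]] | None = None,
    cage: Sequence[GenomicInterval] | None = None,
    ct_table: pd.DataFrame | None = None,
    config: PipelineConfig | None = None,
) -> tuple[list[CandidateRecord], dict[str, int | None]]:
    """Run the staged screen over in-memory inputs.

    Returns per-candidate evidence records (one per transcript that passed the
    exclusivity stage, sorted by descending tumor FPKM) and the funnel summary
    mapping each stage to its survivor count (``None`` = stage not evaluated).
    """
    config = config or PipelineConfig()
    thresholds = config.thresholds

    tumor_sample = _resolve_sample(matrix, "tumor", config.tumor_sample)
    normal_samples = (
        list(config.normal_samples)
        if config.normal_samples is not None
        else matrix.samples_with_role("normal_tissue")
    )

    funnel: dict[str, int | None] = {stage: None for stage in STAGES}

    # stage 1: tumor-exclusive expression
    calls = find_exclusive_transcripts(matrix, tumor_sample, normal_samples, thresholds)
    records = {
        call.transcript_id: CandidateRecord(
            transcript_id=call.transcript_id,
            exclusivity=call,
            stage_reached="exclusive",
        )
        for call in calls
    }
    survivors = [c.transcript_id for c in calls]
    funnel["exclusive"] = len(survivors)

    # stage 2: replicate confirmation
    if replicate is not None and survivors:
        rep_tumor = _resolve_sample(replicate, "tumor", config.tumor_sample)
        kept = confirm_in_replicate(calls, replicate, rep_tumor, thresholds)
        kept_ids = {c.transcript_id for c in kept}
        for tid in survivors:
            if tid in kept_ids:
                records[tid].stage_reached = "confirmed"
            else:
                records[tid].drop_reason = "not confirmed in replicate"
        survivors = [tid for tid in survivors if tid in kept_ids]
        funnel["confirmed"] = len(survivors)
    elif replicate is not None:
        funnel["confirmed"] = 0

    # promoter chromatin annotation: evidence only, never a filter
    if models is not None and tumor_dnase is not None and normal_dnase is not None:
        for tid in survivors:
            model = models.get(tid)
            if model is None:
                continue
            records[tid].promoter = chromatin.annotate_promoter(
                model,
                tumor_dnase,
                normal_dnase,
                feature_tracks=feature_tracks,
                cage=cage,
                upstream=config.upstream,
                downstream=config.downstream,
                cage_slack=config.cage_slack,
            )

    # stage 3: at least one ORF strictly longer than min_len_aa
    if sequences is not None and survivors:
        next_survivors = []
        for tid in survivors:
            seq = sequences.get(tid)
            orfs = find_orfs(seq, config.min_len_aa, tid) if seq is not None else []
            records[tid].orfs = tuple(orfs)
            if orfs:
                records[tid].stage_reached = "has_orf"
                next_survivors.append(tid)
            elif seq is None:
                records[tid].drop_reason = "no sequence available"
            else:
                records[tid].drop_reason = (
                    f"no ORF longer than {config.min_len_aa} aa"
                )
        survivors = next_survivors
        funnel["has_orf"] = len(survivors)
    elif sequences is not None:
        funnel["has_orf"] = 0

    # stage 4: cytoplasmic export
    nuclear = matrix.samples_with_role("nuclear")
    cytoplasmic = matrix.samples_with_role("cytoplasmic")
    if nuclear and cytoplasmic and funnel["has_orf"] is not None:
        nuc_sample, cyt_sample = nuclear[0], cytoplasmic[0]
        next_survivors = []
        for tid in survivors:
            fpkm_nuc = matrix.value(tid, nuc_sample)
            fpkm_cyt = matrix.value(tid, cyt_sample)
            if fpkm_nuc == 0 and fpkm_cyt == 0:
                records[tid].drop_reason = "not expressed in either compartment"
                continue
            loc = call_localization(tid, fpkm_cyt, fpkm_nuc, config.export_threshold)
            records[tid].localization = loc
            if loc.exported:
                records[tid].stage_reached = "exported"
                next_survivors.append(tid)
            else:
                records[tid].drop_reason = "nuclear retained"
        survivors = next_survivors
        funnel["exported"] = len(survivors)

    # stage 5: polysome-fraction translation evidence
    if ct_table is not None and funnel["exported"] is not None:
        profiles = polysome.profiles_from_ct_table(
            ct_table,
            efficiency=config.efficiency,
            bottom_fraction=config.polysome_bottom_fraction,
        )
        next_survivors = []
        for tid in survivors:
            profile = profiles.get(tid)
            if profile is None:
                records[tid].drop_reason = "no polysome profile"
                continue
            score, translated = polysome_enrichment(profile, config.translation_cutoff)
            records[tid].translation_score = score
            records[tid].translated = translated
            if translated:
                records[tid].stage_reached = "translated"
                records[tid].final_candidate = True
                next_survivors.append(tid)
            else:
                records[tid].drop_reason = "not enriched in polysomal fractions"
        survivors = next_survivors
        funnel["translated"] = len(survivors)

    ordered = sorted(
        records.values(),
        key=lambda r: (-r.exclusivity.tumor_fpkm, r.transcript_id),
    )
    return ordered, funnel


def run_screen(
    config: PipelineConfig, base_dir: str | Path = "."
) -> tuple[list[CandidateRecord], dict[str, int | None]]:
    """Load every configured input file and run :func:`screen_cohort`."""
    base = Path(base_dir)
    if config.expression is None or config.samples is None:
        raise ValueError("config must provide 'expression' and 'samples' paths")
    meta = read_sample_metadata(base / config.samples)
    matrix = read_expression_table(base / config.expression, meta)

    replicate = None
    if config.replicate is not None:
        rep_meta = (
            read_sample_metadata(base / config.replicate_samples)
            if config.replicate_samples
            else meta
        )
        replicate = read_expression_table(base / config.replicate, rep_meta)

    sequences = None
    if config.sequences is not None:
        sequences = dict(read_fasta(base / config.sequences))

    models = None
    if config.transcript_models is not None:
        models = read_transcript_models(base / config.transcript_models, sequences)

    def _track(path: str | None):
        return read_bed(base / path) if path is not None else None

    feature_tracks = {
        name: read_bed(base / path) for name, path in config.feature_tracks.items()
    } or None

    ct = read_ct_table(base / config.ct_table) if config.ct_table is not None else None

    return screen_cohort(
        matrix,
        replicate=replicate,
        sequences=sequences,
        models=models,
        tumor_dnase=_track(config.tumor_dnase),
        normal_dnase=_track(config.normal_dnase),
        feature_tracks=feature_tracks,
        cage=_track(config.cage),
        ct_table=ct,
        config=config,
    )


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------


def _interval_to_json(iv: GenomicInterval) -> dict:
    return {
        "chrom": iv.chrom,
        "start": iv.start,
        "end": iv.end,
        "strand": iv.strand,
        "label": iv.label,
    }


def _record_to_json(record: CandidateRecord) -> dict:
    data: dict = {
        "transcript_id": record.transcript_id,
        "exclusivity": asdict(record.exclusivity),
        "stage_reached": record.stage_reached,
        "promoter": None,
        "orfs": [asdict(orf) for orf in record.orfs],
        "localization": asdict(record.localization) if record.localization else None,
        "translation_score": record.translation_score,
        "translated": record.translated,
        "final_candidate": record.final_candidate,
        "drop_reason": record.drop_reason,
    }
    if record.promoter is not None:
        data["promoter"] = {
            "transcript_id": record.promoter.transcript_id,
            "window": _interval_to_json(record.promoter.window),
            "tumor_dnase_peaks": record.promoter.tumor_dnase_peaks,
            "normal_dnase_peaks": record.promoter.normal_dnase_peaks,
            "differential_open": record.promoter.differential_open,
            "feature_counts": dict(record.promoter.feature_counts),
            "cage_supported": record.promoter.cage_supported,
        }
    return data


def _record_from_json(data: dict) -> CandidateRecord:
    promoter = None
    if data["promoter"] is not None:
        p = data["promoter"]
        promoter = PromoterAnnotation(
            transcript_id=p["transcript_id"],
            window=GenomicInterval(**p["window"]),
            tumor_dnase_peaks=p["tumor_dnase_peaks"],
            normal_dnase_peaks=p["normal_dnase_peaks"],
            differential_open=p["differential_open"],
            feature_counts=p["feature_counts"],
            cage_supported=p["cage_supported"],
        )
    return CandidateRecord(
        transcript_id=data["transcript_id"],
        exclusivity=ExclusivityCall(**data["exclusivity"]),
        stage_reached=data["stage_reached"],
        promoter=promoter,
        orfs=tuple(OpenReadingFrame(**orf) for orf in data["orfs"]),
        localization=(
            LocalizationCall(**data["localization"]) if data["localization"] else None
        ),
        translation_score=data["translation_score"],
        translated=data["translated"],
        final_candidate=data["final_candidate"],
        drop_reason=data["drop_reason"],
    )


def write_report(
    records: Sequence[CandidateRecord],
    funnel: Mapping[str, int | None],
    outdir: str | Path,
) -> dict[str, Path]:
    """Write report.json, candidates.tsv and funnel.txt; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    report_json = outdir / "report.json"
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "funnel": dict(funnel),
        "records": [_record_to_json(r) for r in records],
    }
    report_json.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")

    rows = []
    for r in records:
        longest = max((o.length_aa for o in r.orfs), default=0)
        rows.append(
            {
                "transcript_id": r.transcript_id,
                "tumor_fpkm": r.exclusivity.tumor_fpkm,
                "max_normal_fpkm": r.exclusivity.max_normal_fpkm,
                "stage_reached": r.stage_reached,
                "n_orfs": len(r.orfs),
                "longest_orf_aa": longest,
                "differential_open": (
                    r.promoter.differential_open if r.promoter else ""
                ),
                "cage_supported": r.promoter.cage_supported if r.promoter else "",
                "cytoplasmic_fraction": (
                    round(r.localization.cytoplasmic_fraction, 6)
                    if r.localization
                    else ""
                ),
                "polysome_score": (
                    round(r.translation_score, 6)
                    if r.translation_score is not None
                    else ""
                ),
                "final_candidate": r.final_candidate,
                "drop_reason": r.drop_reason or "",
            }
        )
    candidates_tsv = outdir / "candidates.tsv"
    pd.DataFrame(rows).to_csv(candidates_tsv, sep="\t", index=False)

    funnel_txt = outdir / "funnel.txt"
    lines = ["stage\tsurvivors"]
    for stage in STAGES:
        count = funnel.get(stage)
        lines.append(f"{stage}\t{'not_evaluated' if count is None else count}")
    funnel_txt.write_text("\n".join(lines) + "\n")

    return {"json": report_json, "tsv": candidates_tsv, "funnel": funnel_txt}


def read_report(path: str | Path) -> tuple[list[CandidateRecord], dict[str, int | None]]:
    """Reconstruct records and funnel from a report.json (round-trip of write_report)."""
    payload = json.loads(Path(path).read_text())
    if payload.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ValueError(
            f"unsupported report schema {payload.get('schema_version')!r}"
        )
    records = [_record_from_json(d) for d in payload["records"]]
    return records, payload["funnel"]
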