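"""Truth-labelled synthetic input bundles for the whole screen.

The generator emulates the statistical structure of the real inputs: a
tumor/normal-panel FPKM matrix that is mostly zero for planted exclusive
transcripts outside the tumor, an independent replicate tumor dataset,
transcript sequences with ORFs of chosen lengths and Kozak classes planted on
a toy chromosome, tumor-only DNase peaks / cCREs / CAGE clusters at chosen
promoters, nuclear/cytoplasmic compartment FPKMs, and a sucrose-gradient qPCR
CT table whose implied distribution concentrates planted translated
transcripts in the polysomal fractions.

Planted truth is nested the way a staged screen requires:

    translated <= exported <= has-qualifying-ORF <= confirmed <= exclusive

Every generator is deterministic per seed, and ORF planting is
scanner-verified: a generated sequence is re-scanned and resampled (bounded
retries) until it contains exactly the requested qualifying ORFs and no
accidental extras.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_formats import (
    ExpressionMatrix,
    GenomicInterval,
    SampleInfo,
    TranscriptModel,
    write_bed,
    write_ct_table,
    write_expression_table,
    write_fasta,
    write_sample_metadata,
    write_transcript_models,
)
from .expression_screen import ScreenThresholds
from .orf_scan import STOP_CODONS, find_orfs
from .polysome import default_polysome_set

__all__ = [
    "SyntheticTruth",
    "SyntheticTracks",
    "SyntheticBundle",
    "TISSUE_PANEL",
    "DEFAULT_ORF_SPECS",
    "generate_cohort",
    "generate_transcript_sequences",
    "generate_tracks_and_ct",
    "default_screen_bundle",
    "write_bundle",
]

#: Normal-tissue panel: liver plus a 16-member body panel, mirroring a
#: liver-cancer screen against a broad normal-tissue reference.
TISSUE_PANEL: tuple[str, ...] = (
    "liver",
    "adipose",
    "adrenal",
    "brain",
    "breast",
    "colon",
    "foreskin",
    "heart",
    "kidney",
    "lung",
    "ovary",
    "placenta",
    "prostate",
    "skeletal_muscle",
    "testis",
    "thyroid",
    "leukocyte",
)

_ALL_CODONS = [a + b + c for a in "TCAG" for b in "TCAG" for c in "TCAG"]
_SAFE_CODONS = [c for c in _ALL_CODONS if c not in STOP_CODONS]
_NUCLEOTIDES = np.array(list("ACGT"))

#: Default qualifying-ORF structure of the six ORF-bearing candidates: the
#: flagship transcript carries a 52-aa weak-context and a 68-aa strong-context
#: ORF; the others carry two to three ORFs in the 51-72 aa range.
DEFAULT_ORF_SPECS: tuple[tuple[tuple[int, str], ...], ...] = (
    ((52, "weak"), (68, "strong")),
    ((55, "adequate"), (61, "strong")),
    ((72, "strong"), (51, "weak")),
    ((53, "weak"), (57, "adequate"), (66, "strong")),
    ((51, "strong"), (59, "weak")),
    ((60, "adequate"), (54, "strong")),
)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth planted by the generators, one field per screen stage."""

    exclusive_ids: tuple[str, ...]
    confirmed_ids: tuple[str, ...]
    orf_spec: Mapping[str, tuple[tuple[int, str], ...]]  # id -> ((length_aa, kozak), ...)
    exported_ids: tuple[str, ...]
    translated_ids: tuple[str, ...]
    promoter_open_ids: tuple[str, ...]
    seed: int

    def qualifying_orf_ids(self, min_len_aa: int = 50) -> tuple[str, ...]:
        """Transcripts planted with at least one ORF strictly longer than ``min_len_aa``."""
        return tuple(
            tid
            for tid in self.confirmed_ids
            if any(length > min_len_aa for length, _ in self.orf_spec.get(tid, ()))
        )

    def __post_init__(self) -> None:
        chain = [
            ("translated", set(self.translated_ids)),
            ("exported", set(self.exported_ids)),
            ("has-qualifying-ORF", set(self.qualifying_orf_ids())),
            ("confirmed", set(self.confirmed_ids)),
            ("exclusive", set(self.exclusive_ids)),
        ]
        for (inner_name, inner), (outer_name, outer) in zip(chain, chain[1:]):
            if not inner <= outer:
                raise ValueError(
                    f"truth nesting violated: {inner_name} ids must be a subset "
                    f"of {outer_name} ids"
                )
        if not set(self.promoter_open_ids) <= set(self.confirmed_ids):
            raise ValueError("promoter_open_ids must be confirmed transcripts")


@dataclass
class SyntheticTracks:
    """Interval tracks plus the polysome CT table for one synthetic cohort."""

    tumor_dnase: list[GenomicInterval]
    normal_dnase: list[GenomicInterval]
    feature_tracks: dict[str, list[GenomicInterval]]
    cage: list[GenomicInterval]
    ct_table: pd.DataFrame
    polysome_set: frozenset[int]


@dataclass
class SyntheticBundle:
    """Everything one end-to-end screen run consumes, plus its planted truth."""

    matrix: ExpressionMatrix
    replicate: ExpressionMatrix
    truth: SyntheticTruth
    sequences: list[tuple[str, str]]
    models: dict[str, TranscriptModel]
    tracks: SyntheticTracks


def _transcript_ids(n: int) -> list[str]:
    return [f"SYNT{i:06d}.1" for i in range(1, n + 1)]


def _expressed_fpkm(
    rng: np.random.Generator, size: int, median: float, dispersion: float, floor: float
) -> np.ndarray:
    """Log-normal FPKM draws guaranteed to clear ``floor`` (the on-threshold)."""
    return floor + rng.lognormal(mean=math.log(median), sigma=dispersion, size=size)


def generate_cohort(
    n_transcripts: int = 500,
    tissues: Sequence[str] = TISSUE_PANEL,
    n_exclusive: int = 12,
    n_confirmed: int = 9,
    orf_specs: Sequence[tuple[tuple[int, str], ...]] = DEFAULT_ORF_SPECS,
    n_exported: int = 5,
    n_translated: int = 3,
    n_promoter_open: int = 7,
    leakage: float = 0.0,
    dispersion: float = 0.5,
    median_fpkm: float = 30.0,
    thresholds: ScreenThresholds = ScreenThresholds(),
    seed: int = 0,
) -> tuple[ExpressionMatrix, ExpressionMatrix, SyntheticTruth]:
    """Generate a tumor/normal/compartment FPKM matrix, a replicate, and truth.

    Exclusive transcripts draw tumor FPKM log-normally above ``tau_on``
    (median ~30 FPKM) and are exactly zero in every normal tissue; with
    probability ``leakage`` a normal cell flips to a small positive value
    instead, breaking exclusivity for that transcript.  Background transcripts
    are expressed in at least one normal tissue.  The replicate matrix
    re-draws tumor values and zeroes the non-confirmed planted ids.
    Compartment (nuclear/cytoplasmic) samples split each tumor-expressed
    transcript's signal so planted exported ids show a high cytoplasmic
    fraction and the non-exported ORF-bearing candidates a nuclear-retained
    one.
    """
    if n_transcripts < 1:
        raise ValueError("n_transcripts must be positive")
    if not tissues:
        raise ValueError("tissue list must not be empty")
    if not 0.0 <= leakage <= 1.0:
        raise ValueError("leakage must lie in [0, 1]")
    if not (
        n_translated <= n_exported <= len(orf_specs) <= n_confirmed
        <= n_exclusive <= n_transcripts
    ):
        raise ValueError(
            "infeasible truth spec: need n_translated <= n_exported <= "
            "len(orf_specs) <= n_confirmed <= n_exclusive <= n_transcripts"
        )
    if n_promoter_open > n_confirmed:
        raise ValueError("n_promoter_open cannot exceed n_confirmed")

    rng = np.random.default_rng(seed)
    ids = _transcript_ids(n_transcripts)
    planted = list(rng.choice(n_transcripts, size=n_exclusive, replace=False))
    exclusive_ids = tuple(ids[i] for i in planted)
    confirmed_ids = exclusive_ids[:n_confirmed]
    orf_ids = confirmed_ids[: len(orf_specs)]
    exported_ids = orf_ids[:n_exported]
    translated_ids = exported_ids[:n_translated]
    promoter_open_ids = confirmed_ids[:n_promoter_open]
    orf_spec = {tid: tuple(spec) for tid, spec in zip(orf_ids, orf_specs)}
    truth = SyntheticTruth(
        exclusive_ids=exclusive_ids,
        confirmed_ids=confirmed_ids,
        orf_spec=orf_spec,
        exported_ids=exported_ids,
        translated_ids=translated_ids,
        promoter_open_ids=promoter_open_ids,
        seed=seed,
    )

    tissues = list(tissues)
    exclusive_set = set(exclusive_ids)
    tumor = np.zeros(n_transcripts)
    normals = np.zeros((n_transcripts, len(tissues)))
    tumor_on_floor = thresholds.tau_on
    for i, tid in enumerate(ids):
        if tid in exclusive_set:
            tumor[i] = _expressed_fpkm(rng, 1, median_fpkm, dispersion, tumor_on_floor)[0]
            if leakage > 0:
                flips = rng.random(len(tissues)) < leakage
                normals[i, flips] = rng.uniform(0.1, 2.0, size=int(flips.sum()))
        else:
            # background: expressed in >=1 normal tissue, sometimes shared with tumor
            k = int(rng.integers(1, min(4, len(tissues)) + 1))
            cols = rng.choice(len(tissues), size=k, replace=False)
            normals[i, cols] = _expressed_fpkm(rng, k, median_fpkm, dispersion, 0.0)
            if rng.random() < 0.5:
                tumor[i] = _expressed_fpkm(rng, 1, median_fpkm, dispersion, 0.0)[0]

    # compartment split of the tumor signal
    cyt = np.zeros(n_transcripts)
    nuc = np.zeros(n_transcripts)
    exported_set, orf_set = set(exported_ids), set(orf_ids)
    for i, tid in enumerate(ids):
        if tumor[i] == 0:
            continue
        if tid in exported_set:
            frac = rng.uniform(0.6, 0.9)
        elif tid in orf_set:  # ORF-bearing but nuclear-retained
            frac = rng.uniform(0.02, 0.1)
        else:
            frac = rng.uniform(0.3, 0.8)
        cyt[i] = frac * tumor[i]
        nuc[i] = (1.0 - frac) * tumor[i]

    columns = {"tumor": tumor}
    sample_meta = {"tumor": SampleInfo(role="tumor", tissue="hepatoma")}
    for j, tissue in enumerate(tissues):
        sample = f"normal_{tissue}"
        columns[sample] = normals[:, j]
        sample_meta[sample] = SampleInfo(role="normal_tissue", tissue=tissue)
    columns["nuclear"] = nuc
    columns["cytoplasmic"] = cyt
    sample_meta["nuclear"] = SampleInfo(role="nuclear", tissue="hepatoma")
    sample_meta["cytoplasmic"] = SampleInfo(role="cytoplasmic", tissue="hepatoma")
    matrix = ExpressionMatrix(pd.DataFrame(columns, index=ids), sample_meta)

    # independent replicate: redraw tumor, zero the non-confirmed planted ids
    confirmed_set = set(confirmed_ids)
    rep_tumor = np.zeros(n_transcripts)
    for i, tid in enumerate(ids):
        if tid in confirmed_set:
            rep_tumor[i] = _expressed_fpkm(rng, 1, median_fpkm, dispersion, tumor_on_floor)[0]
        elif tid in exclusive_set:
            rep_tumor[i] = 0.0
        elif tumor[i] > 0 and rng.random() < 0.9:
            rep_tumor[i] = _expressed_fpkm(rng, 1, median_fpkm, dispersion, 0.0)[0]
    replicate = ExpressionMatrix(
        pd.DataFrame({"tumor": rep_tumor}, index=ids),
        {"tumor": SampleInfo(role="tumor", tissue="hepatoma")},
    )
    return matrix, replicate, truth


# ---------------------------------------------------------------------------
# sequence planting
# ---------------------------------------------------------------------------


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(_NUCLEOTIDES, size=n)) if n > 0 else ""


def _orf_cassette(rng: np.random.Generator, length_aa: int, kozak: str) -> str:
    """Context + ATG + codons + stop engineering the requested Kozak class."""
    if kozak == "strong":
        minus3, plus4_g = str(rng.choice(["A", "G"])), True
    elif kozak == "weak":
        minus3, plus4_g = str(rng.choice(["C", "T"])), False
    elif kozak == "adequate":
        if rng.random() < 0.5:
            minus3, plus4_g = str(rng.choice(["A", "G"])), False
        else:
            minus3, plus4_g = str(rng.choice(["C", "T"])), True
    else:
        raise ValueError(f"unknown Kozak class {kozak!r}")
    context = minus3 + _random_nt(rng, 2)
    if plus4_g:
        second_pool = [c for c in _SAFE_CODONS if c.startswith("G")]
    else:
        second_pool = [c for c in _SAFE_CODONS if not c.startswith("G")]
    codons = ["ATG"]
    if length_aa > 1:
        codons.append(str(rng.choice(second_pool)))
        codons.extend(rng.choice(_SAFE_CODONS, size=length_aa - 2))
    codons.append(str(rng.choice(sorted(STOP_CODONS))))
    return context + "".join(codons)


def _assemble_sequence(
    rng: np.random.Generator,
    spec: Sequence[tuple[int, str]],
    background_length: int,
) -> str:
    utr5 = 30
    spacer = 21  # multiple of 3 keeps cassettes from sharing frames by accident
    pieces = [_random_nt(rng, utr5)]
    for length_aa, kozak in spec:
        pieces.append(_orf_cassette(rng, length_aa, kozak))
        pieces.append(_random_nt(rng, spacer))
    body = "".join(pieces)
    if len(body) > background_length:
        raise ValueError(
            f"requested ORFs need {len(body)} nt but background_length is "
            f"{background_length}"
        )
    return body + _random_nt(rng, background_length - len(body))


def _matches_spec(
    sequence: str, spec: Sequence[tuple[int, str]], min_len_aa: int
) -> bool:
    expected = sorted((l, k) for l, k in spec if l > min_len_aa)
    found = sorted((o.length_aa, o.kozak) for o in find_orfs(sequence, min_len_aa))
    return expected == found


def generate_transcript_sequences(
    orf_spec: Mapping[str, Sequence[tuple[int, str]]],
    background_length: int = 900,
    min_len_aa: int = 50,
    seed: int = 0,
    max_retries: int = 100,
    chrom: str = "chrS",
    spacing: int = 10_000,
) -> tuple[list[tuple[str, str]], dict[str, TranscriptModel]]:
    """Plant the requested ORFs into random transcripts, scanner-verified.

    ``orf_spec`` maps every transcript id to its (possibly empty) list of
    ``(length_aa, kozak_class)`` requests.  Each candidate sequence is
    re-scanned with :func:`find_orfs`; sequences whose qualifying-ORF content
    differs from the request (an accidental background ORF, an upstream ATG
    extending a planted one...) are resampled, up to ``max_retries`` before a
    hard error.  Transcripts are laid out as single-exon models on a toy
    chromosome, alternating strand.
    """
    rng = np.random.default_rng(seed)
    records: list[tuple[str, str]] = []
    models: dict[str, TranscriptModel] = {}
    for idx, (tid, spec) in enumerate(orf_spec.items()):
        spec = tuple(spec)
        for _ in range(max_retries):
            sequence = _assemble_sequence(rng, spec, background_length)
            if _matches_spec(sequence, spec, min_len_aa):
                break
        else:
            raise RuntimeError(
                f"could not realize ORF spec {spec} for {tid!r} within "
                f"{max_retries} attempts"
            )
        records.append((tid, sequence))
        start = 1000 + idx * spacing
        strand = "+" if idx % 2 == 0 else "-"
        exon = GenomicInterval(chrom, start, start + len(sequence), strand)
        models[tid] = TranscriptModel(
            id=tid,
            chrom=chrom,
            strand=strand,
            exons=(exon,),
            tss=exon.start if strand == "+" else exon.end - 1,
            sequence=sequence,
        )
    return records, models


# ---------------------------------------------------------------------------
# tracks and CT tables
# ---------------------------------------------------------------------------


def generate_tracks_and_ct(
    truth: SyntheticTruth,
    models: Mapping[str, TranscriptModel],
    n_fractions: int = 10,
    ct_noise_sd: float = 0.0,
    polysomal_mass: float = 0.75,
    background_polysomal_mass: float = 0.15,
    ct_offset: float = 20.0,
    efficiency: float = 2.0,
    bottom_fraction: float = 0.4,
    control_id: str = "ACTB",
    seed: int = 0,
) -> SyntheticTracks:
    """Generate DNase/cCRE/CAGE tracks and the polysome-gradient CT table.

    Planted open promoters get a tumor-only DNase peak inside the default
    promoter window, a cCRE mark and a CAGE cluster hugging the TSS; a few
    decoy normal-liver peaks land elsewhere.  CT vectors are built by
    inverting the fraction-distribution formula from a target mass vector
    (planted translated ids put ``polysomal_mass`` in the polysomal fractions,
    everything else ``background_polysomal_mass``) around a global offset
    cycle, then adding Gaussian CT noise.
    """
    if n_fractions < 4:
        raise ValueError("n_fractions must be >= 4")
    if ct_noise_sd < 0:
        raise ValueError("ct_noise_sd must be >= 0")
    rng = np.random.default_rng(seed)

    tumor_dnase: list[GenomicInterval] = []
    normal_dnase: list[GenomicInterval] = []
    ccre: list[GenomicInterval] = []
    cage: list[GenomicInterval] = []
    for tid in truth.promoter_open_ids:
        model = models[tid]
        tss = model.tss
        tumor_dnase.append(
            GenomicInterval(model.chrom, max(0, tss - 50), tss + 50, ".", f"{tid}_dhs")
        )
        ccre.append(
            GenomicInterval(model.chrom, max(0, tss - 20), tss + 30, ".", f"{tid}_ccre")
        )
        cage.append(
            GenomicInterval(model.chrom, max(0, tss - 10), tss + 11, ".", f"{tid}_cage")
        )
    # decoy normal-tissue accessibility away from every candidate promoter
    confirmed = set(truth.confirmed_ids)
    decoys = [tid for tid in models if tid not in confirmed][:5]
    for tid in decoys:
        model = models[tid]
        normal_dnase.append(
            GenomicInterval(
                model.chrom, max(0, model.tss - 50), model.tss + 50, ".", f"{tid}_dhs"
            )
        )

    polysome_set = default_polysome_set(n_fractions, bottom_fraction)
    poly = sorted(polysome_set)
    non_poly = [i for i in range(n_fractions) if i not in polysome_set]
    translated = set(truth.translated_ids)

    def target_mass(mass_in_polysomes: float) -> np.ndarray:
        p = np.empty(n_fractions)
        p[poly] = mass_in_polysomes / len(poly)
        p[non_poly] = (1.0 - mass_in_polysomes) / len(non_poly)
        return p

    rows: dict[str, np.ndarray] = {}
    assayed = list(truth.exported_ids) + [control_id]
    for tid in assayed:
        mass = polysomal_mass if (tid in translated or tid == control_id) else background_polysomal_mass
        p = target_mass(mass)
        ct = ct_offset - np.log(p) / np.log(efficiency)
        if ct_noise_sd > 0:
            ct = ct + rng.normal(0.0, ct_noise_sd, size=n_fractions)
        rows[tid] = ct
    labels = [f"F{i + 1:02d}" for i in range(n_fractions)]
    ct_table = pd.DataFrame.from_dict(rows, orient="index", columns=labels)

    return SyntheticTracks(
        tumor_dnase=tumor_dnase,
        normal_dnase=normal_dnase,
        feature_tracks={"cCRE": ccre},
        cage=cage,
        ct_table=ct_table,
        polysome_set=polysome_set,
    )


def default_screen_bundle(
    seed: int = 0,
    n_transcripts: int = 500,
    leakage: float = 0.0,
    ct_noise_sd: float = 0.0,
    background_length: int = 900,
    min_len_aa: int = 50,
) -> SyntheticBundle:
    """Default study-condition bundle: 12 exclusive, 9 confirmed, 6 ORF-bearing,
    5 exported, 3 translated among ``n_transcripts``, zero noise.

    Sequences are generated for every confirmed candidate plus a background
    sample of fifty non-candidate transcripts (no qualifying ORFs), which is
    what the downstream ORF stage can ever see.
    """
    matrix, replicate, truth = generate_cohort(
        n_transcripts=n_transcripts,
        leakage=leakage,
        seed=seed,
    )
    orf_spec: dict[str, tuple[tuple[int, str], ...]] = {}
    for tid in truth.confirmed_ids:
        orf_spec[tid] = truth.orf_spec.get(tid, ())
    for tid in matrix.transcript_ids:
        if len(orf_spec) >= len(truth.confirmed_ids) + 50:
            break
        if tid not in orf_spec:
            orf_spec[tid] = ()
    sequences, models = generate_transcript_sequences(
        orf_spec,
        background_length=background_length,
        min_len_aa=min_len_aa,
        seed=seed + 1,
    )
    tracks = generate_tracks_and_ct(
        truth, models, ct_noise_sd=ct_noise_sd, seed=seed + 2
    )
    return SyntheticBundle(
        matrix=matrix,
        replicate=replicate,
        truth=truth,
        sequences=sequences,
        models=models,
        tracks=tracks,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> Path:
    """Write a bundle as the exact on-disk formats the pipeline consumes.

    Emits expression/replicate TSVs with sample metadata, a transcript FASTA
    and model table, BED tracks, the CT CSV, the planted-truth JSON and a
    ready-to-run ``config.yaml``; returns the config path.
    """
    import json

    from .pipeline import PipelineConfig

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    write_expression_table(bundle.matrix, outdir / "expression.tsv")
    write_sample_metadata(bundle.matrix.sample_meta, outdir / "samples.tsv")
    write_expression_table(bundle.replicate, outdir / "replicate.tsv")
    write_sample_metadata(bundle.replicate.sample_meta, outdir / "replicate_samples.tsv")
    write_fasta(bundle.sequences, outdir / "transcripts.fasta")
    write_transcript_models(bundle.models.values(), outdir / "transcript_models.tsv")
    write_bed(bundle.tracks.tumor_dnase, outdir / "tumor_dnase.bed")
    write_bed(bundle.tracks.normal_dnase, outdir / "normal_dnase.bed")
    write_bed(bundle.tracks.cage, outdir / "cage.bed")
    feature_paths: dict[str, str] = {}
    for name, track in bundle.tracks.feature_tracks.items():
        fname = f"feature_{name}.bed"
        write_bed(track, outdir / fname)
        feature_paths[name] = fname
    write_ct_table(bundle.tracks.ct_table, outdir / "polysome_ct.csv")

    truth = bundle.truth
    truth_payload = {
        "exclusive_ids": list(truth.exclusive_ids),
        "confirmed_ids": list(truth.confirmed_ids),
        "orf_spec": {
            tid: [[length, kozak] for length, kozak in spec]
            for tid, spec in truth.orf_spec.items()
        },
        "exported_ids": list(truth.exported_ids),
        "translated_ids": list(truth.translated_ids),
        "promoter_open_ids": list(truth.promoter_open_ids),
        "seed": truth.seed,
    }
    (outdir / "truth.json").write_text(json.dumps(truth_payload, indent=2) + "\n")

    config = PipelineConfig(
        seed=truth.seed,
        expression="expression.tsv",
        samples="samples.tsv",
        replicate="replicate.tsv",
        replicate_samples="replicate_samples.tsv",
        sequences="transcripts.fasta",
        transcript_models="transcript_models.tsv",
        tumor_dnase="tumor_dnase.bed",
        normal_dnase="normal_dnase.bed",
        cage="cage.bed",
        feature_tracks=feature_paths,
        ct_table="polysome_ct.csv",
    )
    config_path = outdir / "config.yaml"
    config.to_yaml(config_path)
    return config_path
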