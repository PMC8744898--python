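"""Sense-strand ORF discovery, Kozak-context scoring, translation and peptide mass.

An ORF runs from the 5'-most ATG to its first in-frame stop codon; there is
one ORF per (frame, stop) pair, so downstream in-frame ATGs sharing a stop do
not count separately.  ORFs whose stop would fall beyond the transcript end
are discarded (no read-through).  The length filter is strict: "longer than
50 aa" keeps a 51-aa ORF and rejects a 50-aa one.  Only the three sense-strand
frames are scanned — the transcript itself is the translated molecule.

Kozak context is scored at the two positions that dominate initiation
strength: a purine at -3 (three bases before the A of ATG) and a G at +4 (the
base after the G of ATG).  Both satisfied = strong, exactly one = adequate,
neither = weak; positions outside the sequence count as failing.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

from Bio.Data import CodonTable
from Bio.SeqUtils import molecular_weight

__all__ = [
    "OpenReadingFrame",
    "find_orfs",
    "kozak_class",
    "translate",
    "peptide_mass",
]

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
_STANDARD_TABLE = CodonTable.unambiguous_dna_by_id[1].forward_table
_STANDARD_AA = frozenset("ACDEFGHIKLMNPQRSTVWY")
_NT_ALPHABET = re.compile(r"[^ACGTN]")


@dataclass(frozen=True)
class OpenReadingFrame:
    """One detected ORF on a transcript's sense strand.

    ``start_nt`` is the 0-based offset of the A of the ATG; ``end_nt`` is the
    exclusive offset just past the stop codon; ``length_aa`` excludes the stop.
    """

    transcript_id: str
    frame: int
    start_nt: int
    end_nt: int
    length_aa: int
    peptide: str
    kozak: str  # strong | adequate | weak

    def __post_init__(self) -> None:
        if self.frame not in (0, 1, 2):
            raise ValueError(f"frame must be 0, 1 or 2, got {self.frame}")
        if self.end_nt - self.start_nt != 3 * (self.length_aa + 1):
            raise ValueError("ORF span must equal 3 * (length_aa + 1)")
        if len(self.peptide) != self.length_aa:
            raise ValueError("peptide length must equal length_aa")
        if not self.peptide.startswith("M"):
            raise ValueError("peptide must begin with M")
        if self.start_nt % 3 != self.frame:
            raise ValueError("start_nt must be congruent to frame mod 3")
        if self.kozak not in ("strong", "adequate", "weak"):
            raise ValueError(f"unknown Kozak class {self.kozak!r}")


def _validate_sequence(sequence: str) -> str:
    sequence = sequence.upper()
    bad = _NT_ALPHABET.search(sequence)
    if bad is not None:
        raise ValueError(
            f"illegal character {bad.group()!r} at offset {bad.start()}"
        )
    return sequence


def find_orfs(
    sequence: str, min_len_aa: int = 50, transcript_id: str = ""
) -> list[OpenReadingFrame]:
    """Enumerate sense-strand ORFs strictly longer than ``min_len_aa``.

    Codons containing N never match ATG or a stop.  Output is sorted by
    ``start_nt`` (then frame).
    """
    sequence = _validate_sequence(sequence)
    if min_len_aa < 0:
        raise ValueError("min_len_aa must be >= 0")
    orfs: list[OpenReadingFrame] = []
    for frame in (0, 1, 2):
        open_start: int | None = None
        for pos in range(frame, len(sequence) - 2, 3):
            codon = sequence[pos : pos + 3]
            if codon in STOP_CODONS:
                if open_start is not None:
                    length_aa = (pos - open_start) // 3
                    if length_aa > min_len_aa:
                        cds = sequence[open_start : pos + 3]
                        orfs.append(
                            OpenReadingFrame(
                                transcript_id=transcript_id,
                                frame=frame,
                                start_nt=open_start,
                                end_nt=pos + 3,
                                length_aa=length_aa,
                                peptide=translate(cds),
                                kozak=kozak_class(sequence, open_start),
                            )
                        )
                    open_start = None
            elif codon == "ATG" and open_start is None:
                open_start = pos
        # an ATG still open here lacks an in-frame stop: discarded
    orfs.sort(key=lambda o: (o.start_nt, o.frame))
    return orfs


def kozak_class(sequence: str, start_nt: int) -> str:
    """Score the initiation context of the ATG at ``start_nt``."""
    sequence = sequence.upper()
    if sequence[start_nt : start_nt + 3] != "ATG":
        raise ValueError(f"no ATG at offset {start_nt}")
    purine_at_minus3 = start_nt >= 3 and sequence[start_nt - 3] in "AG"
    g_at_plus4 = start_nt + 3 < len(sequence) and sequence[start_nt + 3] == "G"
    if purine_at_minus3 and g_at_plus4:
        return "strong"
    if purine_at_minus3 or g_at_plus4:
        return "adequate"
    return "weak"


def translate(cds: str) -> str:
    """Translate an ATG-initiated CDS with the standard genetic code.

    A trailing stop codon is dropped; an internal stop is an error; any codon
    containing N translates to X.
    """
    cds = _validate_sequence(cds)
    if len(cds) % 3 != 0:
        raise ValueError(f"CDS length {len(cds)} not divisible by 3")
    if not cds.startswith("ATG"):
        raise ValueError("CDS must begin with ATG")
    codons = [cds[i : i + 3] for i in range(0, len(cds), 3)]
    peptide: list[str] = []
    for i, codon in enumerate(codons):
        if codon in STOP_CODONS:
            if i != len(codons) - 1:
                raise ValueError(f"internal stop codon {codon} at codon {i}")
            break
        peptide.append("X" if "N" in codon else _STANDARD_TABLE[codon])
    return "".join(peptide)


def peptide_mass(peptide: str) -> float:
    """Average molecular mass of a peptide in daltons, to 0.01 Da.

    Sum of average residue masses plus one water; average (not monoisotopic)
    masses match kDa-scale gel estimates.  X is disallowed.
    """
    if not peptide:
        raise ValueError("peptide must be non-empty")
    bad = set(peptide) - _STANDARD_AA
    if bad:
        raise ValueError(f"non-standard residue(s) {sorted(bad)} in peptide")
    return round(molecular_weight(peptide, seq_type="protein"), 2)
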