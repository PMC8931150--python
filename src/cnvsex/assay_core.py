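"""Two-gene assay definitions and the specimen data model.

A copy-number sexing assay for an X0/XX species pairs an X-linked *target*
gene (one copy in males, two in females) with an autosomal single-copy
*reference* gene (two copies in both sexes).  This module holds the marker
definitions — primer sequences, genomic coordinates, expected amplicon
sizes — and validates their internal consistency.

Coordinates are 1-based inclusive on both ends, the convention under which
``amplicon length = reverse_end - forward_start + 1`` reproduces the sizes
a gel would show for these markers.
"""

from __future__ import annotations

import tomllib
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Optional

__all__ = [
    "GeneRole",
    "GeneAssay",
    "Specimen",
    "LifeStage",
    "amplicon_length",
    "validate_assay",
    "load_assays",
    "primers_to_fasta",
    "LDVSSC",
    "LDUBE3B",
    "DEFAULT_ASSAYS",
]

_DNA_ALPHABET = frozenset("ACGT")


class GeneRole(str, Enum):
    """Role of a marker in the two-gene dosage assay."""

    TARGET = "target"
    REFERENCE = "reference"


class LifeStage(str, Enum):
    ADULT = "adult"
    LARVA_INSTAR_1 = "larva_instar_1"
    LARVA_INSTAR_2 = "larva_instar_2"
    LARVA_INSTAR_3 = "larva_instar_3"
    LARVA_INSTAR_4 = "larva_instar_4"


class CoordinateOrderError(ValueError):
    """Reverse-primer end precedes forward-primer start."""


@dataclass(frozen=True)
class GeneAssay:
    """One marker of the two-gene assay.

    Spans are (start, end) 1-based inclusive genomic positions of the
    primer annealing sites; the amplicon runs from the forward primer's
    first base to the reverse primer's last base.
    """

    gene_name: str
    role: GeneRole
    scaffold_accession: str
    forward_primer_seq: str
    reverse_primer_seq: str
    forward_span: tuple[int, int]
    reverse_span: tuple[int, int]
    expected_amplicon_bp: int


@dataclass(frozen=True)
class Specimen:
    """One individual in a collection; ``true_sex`` is absent for larvae."""

    specimen_id: str
    collection_id: str = ""
    life_stage: LifeStage = LifeStage.ADULT
    true_sex: Optional[str] = None  # "F" | "M" | None
    run_id: str = ""


def amplicon_length(forward_start: int, reverse_end: int) -> int:
    """Length in bp of the amplicon spanned by 1-based inclusive coordinates.

    Raises :class:`CoordinateOrderError` if ``reverse_end < forward_start``.
    """
    if reverse_end < forward_start:
        raise CoordinateOrderError(
            f"reverse end {reverse_end} precedes forward start {forward_start}"
        )
    return reverse_end - forward_start + 1


def validate_assay(assay: GeneAssay) -> list[str]:
    """Check an assay definition; return a list of violations (empty = valid).

    Violations are reported, never raised, so a plate of assays can be
    screened in one pass.  The input is not mutated.
    """
    violations: list[str] = []
    fs, fe = assay.forward_span
    rs, re_ = assay.reverse_span
    if not (fs <= fe):
        violations.append(f"{assay.gene_name}: forward span reversed ({fs} > {fe})")
    if not (fe < rs):
        violations.append(
            f"{assay.gene_name}: forward span must end before reverse span starts"
            f" ({fe} >= {rs})"
        )
    if not (rs <= re_):
        violations.append(f"{assay.gene_name}: reverse span reversed ({rs} > {re_})")
    for label, seq in (("forward", assay.forward_primer_seq),
                       ("reverse", assay.reverse_primer_seq)):
        bad = set(seq.upper()) - _DNA_ALPHABET
        if bad:
            violations.append(
                f"{assay.gene_name}: {label} primer contains non-ACGT symbols "
                f"{sorted(bad)}"
            )
    if fs <= re_:
        computed = amplicon_length(fs, re_)
        if computed != assay.expected_amplicon_bp:
            violations.append(
                f"{assay.gene_name}: declared amplicon {assay.expected_amplicon_bp} bp"
                f" but coordinates span {computed} bp"
            )
    if assay.expected_amplicon_bp <= 0:
        violations.append(f"{assay.gene_name}: amplicon size must be positive")
    return violations


def load_assays(path: str | Path) -> list[GeneAssay]:
    """Load assay definitions from a TOML file.

    Expected layout::

        [[assay]]
        gene_name = "LdVssc"
        role = "target"
        scaffold_accession = "NW_019291534.1"
        forward_primer_seq = "AGAATCATGGATTGTCCGAAGGTT"
        reverse_primer_seq = "GAGGGTGGTAAGAGTGGCAAAAGT"
        forward_span = [14058, 14081]
        reverse_span = [14277, 14300]
        expected_amplicon_bp = 243
    """
    with open(path, "rb") as fh:
        doc = tomllib.load(fh)
    assays = []
    for entry in doc.get("assay", []):
        assays.append(
            GeneAssay(
                gene_name=entry["gene_name"],
                role=GeneRole(entry["role"]),
                scaffold_accession=entry.get("scaffold_accession", ""),
                forward_primer_seq=entry["forward_primer_seq"],
                reverse_primer_seq=entry["reverse_primer_seq"],
                forward_span=tuple(entry["forward_span"]),
                reverse_span=tuple(entry["reverse_span"]),
                expected_amplicon_bp=int(entry["expected_amplicon_bp"]),
            )
        )
    return assays


def primers_to_fasta(assays: list[GeneAssay]) -> str:
    """Render primer sequences as FASTA, one record per primer.

    Headers follow ``>gene_name|role|F`` / ``>gene_name|role|R``.
    """
    lines = []
    for a in assays:
        lines.append(f">{a.gene_name}|{a.role.value}|F")
        lines.append(a.forward_primer_seq)
        lines.append(f">{a.gene_name}|{a.role.value}|R")
        lines.append(a.reverse_primer_seq)
    return "\n".join(lines) + "\n"


# Published marker pair for Leptinotarsa decemlineata: the X-linked
# voltage-sensitive sodium channel gene (target) and the autosomal
# ubiquitin-protein ligase E3B gene (reference).
LDVSSC = GeneAssay(
    gene_name="LdVssc",
    role=GeneRole.TARGET,
    scaffold_accession="NW_019291534.1",
    forward_primer_seq="AGAATCATGGATTGTCCGAAGGTT",
    reverse_primer_seq="GAGGGTGGTAAGAGTGGCAAAAGT",
    forward_span=(14058, 14081),
    reverse_span=(14277, 14300),
    expected_amplicon_bp=243,
)

LDUBE3B = GeneAssay(
    gene_name="LdUBE3B",
    role=GeneRole.REFERENCE,
    scaffold_accession="NW_019289582.1",
    forward_primer_seq="AACAACTGCAGCATCTGAAACTCC",
    reverse_primer_seq="TACGGCTTTGAACACTTTGACACA",
    forward_span=(72367, 72390),
    reverse_span=(72593, 72616),
    expected_amplicon_bp=250,
)

DEFAULT_ASSAYS: tuple[GeneAssay, GeneAssay] = (LDVSSC, LDUBE3B)
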