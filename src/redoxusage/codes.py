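"""Genetic-code tables and per-amino-acid codon gains/losses.

Animal mitochondria translate with variant genetic codes (NCBI tables 2,
5, 9, 13, 14 among others) in which codons are reassigned relative to the
standard code — most famously UGA from stop to tryptophan. This module
wraps the NCBI translation tables and summarizes, per amino acid, which
codons a variant code gains or loses against a reference code, and how
many species in a panel carry each change.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio.Data import CodonTable as _BioCodonTable

from ._aa import AMINO_ACIDS
from .errors import ConfigurationError, DataError

STOP = "*"

#: NCBI translation-table ids embedded for the study's taxa: standard (1),
#: vertebrate (2), mold/protozoan (4), invertebrate (5), echinoderm (9),
#: ascidian (13) and alternative flatworm (14) mitochondrial codes.
SUPPORTED_CODE_IDS: tuple[int, ...] = (1, 2, 4, 5, 9, 13, 14)


@dataclass(frozen=True)
class CodeTable:
    """A genetic-code table: all 64 RNA codons mapped to an amino acid or stop."""

    id: int
    name: str
    codons: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.codons) != 64:
            raise DataError(
                f"code table {self.id} has {len(self.codons)} codons, expected 64"
            )
        bad = set(self.codons.values()) - set(AMINO_ACIDS) - {STOP}
        if bad:
            raise DataError(f"code table {self.id} maps to unknown symbols {bad}")

    def translate(self, codon: str) -> str:
        """Amino acid (or ``*`` for stop) encoded by an RNA or DNA codon."""
        codon = codon.upper().replace("T", "U")
        if codon not in self.codons:
            raise DataError(f"invalid codon {codon!r}")
        return self.codons[codon]


def get_code_table(code_id: int) -> CodeTable:
    """Load an NCBI translation table by id (RNA alphabet)."""
    if code_id not in SUPPORTED_CODE_IDS:
        raise ConfigurationError(
            f"unknown genetic code id {code_id}; known ids: {SUPPORTED_CODE_IDS}"
        )
    bio = _BioCodonTable.unambiguous_rna_by_id[code_id]
    codons = dict(bio.forward_table)
    for stop in bio.stop_codons:
        codons[stop] = STOP
    return CodeTable(id=code_id, name=bio.names[0], codons=codons)


def codon_count(code: CodeTable, amino_acid: str) -> int:
    """Number of codons translating to `amino_acid` (or ``*``) in `code`."""
    if amino_acid not in set(AMINO_ACIDS) | {STOP}:
        raise DataError(f"unknown amino acid {amino_acid!r}")
    return sum(1 for aa in code.codons.values() if aa == amino_acid)


@dataclass
class CodeDelta:
    """Codon gains and losses per amino acid between two code tables."""

    code_id: int
    reference_id: int
    gained: dict[str, set[str]] = field(default_factory=dict)
    lost: dict[str, set[str]] = field(default_factory=dict)

    def is_empty(self) -> bool:
        return not self.gained and not self.lost


def decoding_delta(code: CodeTable, reference: CodeTable) -> CodeDelta:
    """For every codon translated differently by `code` and `reference`,
    record a loss for the reference amino acid and a gain for the new one.
    Stop reassignments are included under the ``*`` symbol."""
    delta = CodeDelta(code_id=code.id, reference_id=reference.id)
    for codon, ref_aa in reference.codons.items():
        new_aa = code.codons[codon]
        if new_aa != ref_aa:
            delta.lost.setdefault(ref_aa, set()).add(codon)
            delta.gained.setdefault(new_aa, set()).add(codon)
    return delta


def summarize_decoding(species: pd.DataFrame,
                       reference_id: int = 1,
                       include_stop: bool = False) -> dict[str, str]:
    """Per-amino-acid decoding-change summary over a species panel.

    `species` needs a ``mito_code_id`` column. For each amino acid, every
    codon gained or lost relative to the reference code is annotated with
    the number of species whose mitochondrial code carries that change,
    rendered like ``"+UGA (20/20)"`` or ``"-AUA (19/20)"``. Amino acids
    without changes are omitted; the stop symbol ``*`` is included only
    with ``include_stop=True``. Accounting is symmetric: a codon
    reassigned from one amino acid to another counts as a loss for the
    former and a gain for the latter in every species concerned.
    """
    if "mito_code_id" not in species.columns:
        raise DataError("species table lacks a mito_code_id column")
    reference = get_code_table(reference_id)
    n_total = len(species)
    # per amino acid: (sign, codon) -> number of species with that change
    counts: dict[str, dict[tuple[str, str], int]] = defaultdict(
        lambda: defaultdict(int))
    for code_id, group in species.groupby("mito_code_id"):
        delta = decoding_delta(get_code_table(int(code_id)), reference)
        n_species = len(group)
        for aa, codons in delta.gained.items():
            for codon in codons:
                counts[aa][("+", codon)] += n_species
        for aa, codons in delta.lost.items():
            for codon in codons:
                counts[aa][("-", codon)] += n_species
    summary: dict[str, str] = {}
    symbols = list(AMINO_ACIDS) + ([STOP] if include_stop else [])
    for aa in symbols:
        if aa not in counts:
            continue
        # group codons sharing sign and species count into one clause
        grouped: dict[tuple[str, int], list[str]] = defaultdict(list)
        for (sign, codon), n in counts[aa].items():
            grouped[(sign, n)].append(codon)
        clauses = []
        for (sign, n), codons in sorted(grouped.items(),
                                        key=lambda kv: (-kv[0][1], kv[0][0])):
            body = ", ".join(f"{sign}{c}" for c in sorted(codons))
            clauses.append(f"{body} ({n}/{n_total})")
        summary[aa] = "; ".join(clauses)
    return summary
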