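"""Readers and writers for the external formats, plus sequence inclusion filters.

Formats handled: FASTA protein sets, TMHMM-2.0 transmembrane annotation
output (long and short form), a species metadata TSV, and Newick trees.
The coordinate convention for transmembrane segments is 1-based inclusive
throughout. Readers reject malformed input with typed errors rather than
silently coercing it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import dendropy
import pandas as pd
from Bio import SeqIO
from Bio.SeqRecord import SeqRecord
from Bio.Seq import Seq

from ._aa import AMINO_ACIDS, AMBIGUITY_LETTERS
from .errors import ConfigurationError, DataError, FormatError

logger = logging.getLogger(__name__)

_VALID_LETTERS = set(AMINO_ACIDS) | set(AMBIGUITY_LETTERS) | {"*"}

#: Default description patterns excluded during proteome assembly: partial
#: sequences, and isoforms numbered X2 and higher (the first-listed isoform
#: is kept).
DEFAULT_EXCLUDE_PATTERNS: tuple[str, ...] = (
    r"partial",
    r"isoform X(?:[2-9]|[1-9]\d+)\b",
)


@dataclass(frozen=True)
class ProteinRecord:
    """One protein sequence with its header metadata."""

    id: str
    description: str
    sequence: str
    species_id: str = ""

    def __post_init__(self) -> None:
        if not self.sequence:
            raise DataError(f"protein {self.id!r} has an empty sequence")


@dataclass
class TmdAnnotationSet:
    """Per-protein transmembrane segments, 1-based inclusive, disjoint, sorted."""

    segments: dict[str, list[tuple[int, int]]] = field(default_factory=dict)

    def add(self, protein_id: str, start: int, end: int) -> None:
        if not (1 <= start <= end):
            raise DataError(
                f"invalid segment ({start}, {end}) for {protein_id!r}: "
                "need 1 <= start <= end"
            )
        segs = self.segments.setdefault(protein_id, [])
        segs.append((start, end))
        segs.sort()
        for (s1, e1), (s2, _) in zip(segs, segs[1:]):
            if s2 <= e1:
                raise DataError(
                    f"overlapping segments around ({s1}, {e1}) on {protein_id!r}"
                )

    def for_protein(self, protein_id: str) -> list[tuple[int, int]]:
        return self.segments.get(protein_id, [])

    def validate_against(self, proteins: Iterable[ProteinRecord]) -> None:
        """Check every segment lies within its protein's sequence bounds."""
        lengths = {p.id: len(p.sequence) for p in proteins}
        for pid, segs in self.segments.items():
            if pid not in lengths:
                raise DataError(f"annotation refers to unknown protein {pid!r}")
            for start, end in segs:
                if end > lengths[pid]:
                    raise DataError(
                        f"segment ({start}, {end}) exceeds length "
                        f"{lengths[pid]} of {pid!r}"
                    )

    def __len__(self) -> int:
        return sum(len(v) for v in self.segments.values())


def read_fasta(path: str | Path, species_id: str = "") -> list[ProteinRecord]:
    """Read a protein FASTA file into a list of :class:`ProteinRecord`.

    The header token before the first whitespace is the id, the remainder
    the description. Sequences are uppercased. Ambiguity letters
    (B, J, O, U, X, Z) pass with a warning; other letters are rejected.
    """
    path = Path(path)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper().rstrip("*")
        if rec.id in seen:
            raise FormatError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        bad = set(seq) - _VALID_LETTERS
        if bad:
            raise FormatError(
                f"illegal residue letters {sorted(bad)} in {rec.id!r} ({path})"
            )
        if set(seq) & AMBIGUITY_LETTERS:
            logger.warning("protein %s contains ambiguity residues", rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            ProteinRecord(id=rec.id, description=desc, sequence=seq,
                          species_id=species_id)
        )
    if not records:
        raise FormatError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Sequence[ProteinRecord], path: str | Path,
                width: int = 60) -> None:
    """Write protein records as FASTA wrapped to `width` columns."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(seq_records)


def filter_proteins(
    records: Sequence[ProteinRecord],
    exclude_patterns: Sequence[str] = DEFAULT_EXCLUDE_PATTERNS,
) -> list[ProteinRecord]:
    """Drop records whose description matches any exclusion pattern.

    Patterns are case-insensitive regular expressions; removal counts per
    pattern are logged. An empty pattern list is the identity.
    """
    compiled = []
    for pat in exclude_patterns:
        try:
            compiled.append(re.compile(pat, re.IGNORECASE))
        except re.error as exc:
            raise ConfigurationError(f"invalid exclusion pattern {pat!r}: {exc}")
    removed = {pat: 0 for pat in exclude_patterns}
    kept: list[ProteinRecord] = []
    for rec in records:
        hit = None
        for pat, rx in zip(exclude_patterns, compiled):
            if rx.search(rec.description):
                hit = pat
                break
        if hit is None:
            kept.append(rec)
        else:
            removed[hit] += 1
    for pat, n in removed.items():
        if n:
            logger.info("filter_proteins: removed %d records matching %r", n, pat)
    return kept


def parse_tmhmm(path: str | Path) -> TmdAnnotationSet:
    """Parse TMHMM 2.0 output (long or short form) into a TmdAnnotationSet.

    Long form: tab-separated lines ``<id>\\tTMHMM2.0\\t<topology>\\t<start>\\t<end>``,
    of which only ``TMhelix`` lines contribute segments. Short form: one
    line per protein with ``Topology=`` such as ``o10-32i40-62o``, expanded
    to segments. Comment lines (``#``) are skipped.
    """
    path = Path(path)
    annotations = TmdAnnotationSet()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) >= 5 and fields[1].startswith("TMHMM"):
                pid, _, topo, start_s, end_s = fields[:5]
                if topo != "TMhelix":
                    # inside/outside topology lines carry no segment
                    annotations.segments.setdefault(pid, [])
                    continue
                try:
                    start, end = int(start_s), int(end_s)
                except ValueError:
                    raise FormatError(
                        f"{path}:{lineno}: non-integer coordinates in {line!r}"
                    )
                annotations.add(pid, start, end)
            elif "Topology=" in line:
                pid = fields[0].split()[0]
                annotations.segments.setdefault(pid, [])
                topo = line.split("Topology=", 1)[1].split()[0]
                for m in re.finditer(r"(\d+)-(\d+)", topo):
                    annotations.add(pid, int(m.group(1)), int(m.group(2)))
            elif "PredHel=0" in line or "Len=" in line:
                pid = fields[0].split()[0]
                annotations.segments.setdefault(pid, [])
            else:
                raise FormatError(f"{path}:{lineno}: unrecognized line {line!r}")
    return annotations


def write_tmhmm(annotations: TmdAnnotationSet, path: str | Path) -> None:
    """Write annotations in TMHMM 2.0 long form (TMhelix lines only)."""
    with open(path, "w") as fh:
        for pid in sorted(annotations.segments):
            segs = annotations.segments[pid]
            if not segs:
                fh.write(f"{pid}\tTMHMM2.0\toutside\t1\t1\n")
            for start, end in segs:
                fh.write(f"{pid}\tTMHMM2.0\tTMhelix\t{start}\t{end}\n")


SPECIES_COLUMNS = ("species_id", "name", "lifespan_years", "body_mass_kg",
                   "group", "mito_code_id")


def read_species_metadata(path: str | Path) -> pd.DataFrame:
    """Read the species metadata TSV; validates columns and positivity."""
    df = pd.read_csv(path, sep="\t", dtype={"species_id": str, "name": str,
                                            "group": str})
    missing = set(SPECIES_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"species TSV missing columns: {sorted(missing)}")
    if df["species_id"].duplicated().any():
        raise FormatError("duplicate species_id values in species TSV")
    if (df["lifespan_years"] <= 0).any() or (df["body_mass_kg"] <= 0).any():
        raise FormatError("lifespan_years and body_mass_kg must be positive")
    df["mito_code_id"] = df["mito_code_id"].astype(int)
    return df.set_index("species_id", drop=False)


def write_species_metadata(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", index=False, columns=list(SPECIES_COLUMNS))


def read_newick(path: str | Path,
                species_ids: Iterable[str] | None = None) -> dendropy.Tree:
    """Read a Newick tree; optionally check tips are a subset of species ids."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except Exception as exc:  # dendropy raises a mix of error types
        raise FormatError(f"cannot parse Newick file {path}: {exc}")
    tips = {leaf.taxon.label for leaf in tree.leaf_node_iter()}
    if species_ids is not None:
        unknown = tips - set(species_ids)
        if unknown:
            raise DataError(
                f"tree tips absent from species metadata: {sorted(unknown)}"
            )
    return tree
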