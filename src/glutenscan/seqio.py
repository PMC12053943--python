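"""Sequence and motif database I/O.

Protein databases are plain multi-record FASTA files.  Records carry a
species label, a fragment flag (partial sequences are excluded from
homologue calls downstream) and free-form curation tags such as
``"glupro"`` or ``"allergen:<id>"``.

Motif databases are lists of celiac-active peptide sequences, either a
single sequence per line or CSV/TSV with ``motif_id,sequence`` columns.
"""

from __future__ import annotations

import csv
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: the 20 standard amino acids
STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")

#: residues accepted in database sequences (X = unknown residue)
DEFAULT_ALPHABET = STANDARD_RESIDUES | {"X"}


@dataclass
class ProteinRecord:
    """One database protein sequence.

    Parameters
    ----------
    accession:
        Unique identifier within a database.
    description:
        Free-text header remainder.
    sequence:
        Uppercase amino-acid string (standard 20 letters plus optional X).
    species:
        Controlled label, e.g. ``"wheat"``, ``"barley"``, ``"rye"``,
        ``"oats"`` or ``"other"``.
    is_fragment:
        True for partial sequences (detected from the header by default);
        fragment records are discarded from homologue calls.
    tags:
        Curation labels such as ``"glupro"``, a gluten type, or
        ``"allergen:<id>"``.
    """

    accession: str
    description: str = ""
    sequence: str = ""
    species: str = "other"
    is_fragment: bool = False
    tags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty sequence for accession {self.accession!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class MotifRecord:
    """A short celiac-active (or consensus-epitope) peptide motif."""

    motif_id: str
    sequence: str
    source: str = "CD-active"

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"empty motif sequence for {self.motif_id!r}")


def _validate_sequence(accession: str, seq: str, alphabet: frozenset[str] | set[str]) -> None:
    for pos, ch in enumerate(seq):
        if ch not in alphabet:
            raise ValueError(
                f"illegal residue {ch!r} at position {pos} in record {accession!r}"
            )


def read_fasta(
    path: str | os.PathLike,
    species: str = "other",
    fragment_markers: Sequence[str] = ("Fragment",),
    alphabet: Iterable[str] = DEFAULT_ALPHABET,
    tags: Iterable[str] = (),
) -> list[ProteinRecord]:
    """Read a protein FASTA file into :class:`ProteinRecord` objects.

    Sequences are uppercased and terminal ``*`` stop characters stripped.
    A record is flagged ``is_fragment`` when its header contains any of
    the ``fragment_markers`` substrings (UniProt writes ``(Fragment)``).

    Raises
    ------
    ValueError
        For an empty file, a duplicate accession, or a residue outside
        the accepted alphabet.
    """
    alphabet = frozenset(alphabet)
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    base_tags = set(tags)
    for rec in SeqIO.parse(os.fspath(path), "fasta"):
        header = rec.description
        seq = str(rec.seq).upper().strip("*")
        if rec.id in seen:
            raise ValueError(f"duplicate accession {rec.id!r} in {path}")
        seen.add(rec.id)
        _validate_sequence(rec.id, seq, alphabet)
        is_fragment = any(marker in header for marker in fragment_markers)
        records.append(
            ProteinRecord(
                accession=rec.id,
                description=header[len(rec.id) :].strip(),
                sequence=seq,
                species=species,
                is_fragment=is_fragment,
                tags=set(base_tags),
            )
        )
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records to FASTA (round-trips with :func:`read_fasta`)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.accession, description=r.description)
        for r in records
    ]
    with open(path, "w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=width)
        writer.write_file(seq_records)


def read_motif_db(
    source: str | os.PathLike | Iterable[str],
    source_label: str = "CD-active",
) -> tuple[list[MotifRecord], list[str]]:
    """Read a motif database.

    ``source`` may be a path to a one-sequence-per-line text file, a CSV
    or TSV with ``motif_id,sequence`` columns (header optional), or an
    in-memory iterable of sequences.  Missing ids are auto-generated as
    ``M0001`` etc.  Duplicate sequences are retained but reported in the
    returned warning list.

    Returns
    -------
    (motifs, warnings)
    """
    rows: list[tuple[str | None, str]]
    if isinstance(source, (str, os.PathLike)):
        with open(source) as fh:
            text = fh.read()
        rows = _parse_motif_text(text)
    else:
        rows = [(None, s) for s in source]

    if not rows:
        raise ValueError("motif database is empty")

    motifs: list[MotifRecord] = []
    warnings: list[str] = []
    seen_seq: dict[str, str] = {}
    seen_ids: set[str] = set()
    for i, (motif_id, seq) in enumerate(rows, start=1):
        seq = seq.strip().upper()
        if not seq:
            raise ValueError(f"empty motif sequence at row {i}")
        if motif_id is None:
            motif_id = f"M{i:04d}"
        if motif_id in seen_ids:
            raise ValueError(f"duplicate motif_id {motif_id!r}")
        seen_ids.add(motif_id)
        if seq in seen_seq:
            warnings.append(
                f"duplicate motif sequence {seq!r}: {motif_id} repeats {seen_seq[seq]}"
            )
        else:
            seen_seq[seq] = motif_id
        motifs.append(MotifRecord(motif_id=motif_id, sequence=seq, source=source_label))
    return motifs, warnings


def _parse_motif_text(text: str) -> list[tuple[str | None, str]]:
    lines = [ln.strip() for ln in text.splitlines() if ln.strip()]
    if not lines:
        return []
    delim = "\t" if "\t" in lines[0] else ("," if "," in lines[0] else None)
    if delim is None:
        return [(None, ln) for ln in lines]
    reader = csv.reader(io.StringIO("\n".join(lines)), delimiter=delim)
    rows = list(reader)
    # drop a header row if present
    if rows and rows[0] and rows[0][0].lower() in {"motif_id", "id"}:
        rows = rows[1:]
    out: list[tuple[str | None, str]] = []
    for row in rows:
        if len(row) == 1:
            out.append((None, row[0]))
        else:
            out.append((row[0].strip() or None, row[1]))
    return out


def read_membership_list(path: str | os.PathLike) -> set[str]:
    """Read an accession membership list (one accession per line)."""
    with open(path) as fh:
        return {ln.strip() for ln in fh if ln.strip()}


def filter_by_membership(
    records: Sequence[ProteinRecord], allowed: set[str]
) -> list[ProteinRecord]:
    """Keep only records whose accession is in ``allowed``, preserving order.

    Mirrors restricting identifications to reference-genome or curated
    gluten accession lists; purely accession-based, no sequence
    deduplication.
    """
    return [r for r in records if r.accession in allowed]
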