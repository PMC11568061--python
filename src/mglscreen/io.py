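"""Plain-text readers and writers: FASTA, Stockholm, aligned FASTA, TSV.

All sequence data in the package flows through :class:`ProteinRecord`
(a single protein with optional taxonomy and truth label) and
:class:`Msa` (an aligned block). Positions exposed anywhere in the
package are 1-based, matching the Cys116 / Lys240 convention used for
the methioninase active site.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import AlignIO

from .errors import (
    AlignmentShapeError,
    DuplicateIdError,
    EmptyInputError,
    FastaParseError,
    SchemaError,
)

logger = logging.getLogger(__name__)

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
#: Residues accepted in a normalized sequence.
ALPHABET = frozenset(AMINO_ACIDS + "X")
#: Ambiguity / rare letters folded into X on input.
_FOLD_TO_X = {"B", "Z", "U", "O", "J"}
_GAP_CHARS = {"-", "."}


def normalize_sequence(raw: str, *, line: int | None = None, keep_gaps: bool = False) -> str:
    """Upper-case, strip whitespace and terminal stops, fold B/Z/U/O/J to X.

    Raises :class:`FastaParseError` (with ``line`` when known) on any
    character outside the 20 amino acids, X, ``*`` and gap characters.
    """
    seq = "".join(raw.split()).upper()
    while seq.endswith("*"):
        seq = seq[:-1]
    out = []
    for ch in seq:
        if ch in _GAP_CHARS:
            if keep_gaps:
                out.append("-")
            continue
        if ch in _FOLD_TO_X:
            logger.warning("ambiguous residue %r folded to X", ch)
            out.append("X")
            continue
        if ch not in ALPHABET:
            raise FastaParseError(f"illegal residue character {ch!r}", line=line)
        out.append(ch)
    return "".join(out)


@dataclass
class ProteinRecord:
    """One protein sequence with optional lineage and truth label."""

    id: str
    sequence: str
    description: str = ""
    taxonomy: str | None = None
    truth_label: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise FastaParseError("record id must be non-empty")
        if not self.sequence:
            raise EmptyInputError(f"record {self.id!r} has an empty sequence")
        bad = set(self.sequence) - ALPHABET
        if bad:
            raise FastaParseError(
                f"record {self.id!r} contains illegal residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Msa:
    """A multiple sequence alignment: (id, gapped row) pairs of equal length."""

    records: list[tuple[str, str]]
    length: int = field(init=False)

    def __post_init__(self) -> None:
        if not self.records:
            raise EmptyInputError("alignment has no rows")
        lengths = {len(row) for _, row in self.records}
        if len(lengths) != 1:
            raise AlignmentShapeError(
                f"rows have unequal lengths: {sorted(lengths)}"
            )
        self.length = lengths.pop()
        ids = [rid for rid, _ in self.records]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise DuplicateIdError(f"duplicate row id {dup!r}")
        for rid, row in self.records:
            degapped = row.replace("-", "")
            if not degapped:
                raise EmptyInputError(f"row {rid!r} is all gaps")
            bad = set(degapped) - ALPHABET
            if bad:
                raise FastaParseError(
                    f"row {rid!r} contains illegal residues {sorted(bad)}"
                )

    def degapped(self, index: int) -> str:
        return self.records[index][1].replace("-", "")


def read_fasta(path) -> list[ProteinRecord]:
    """Read protein FASTA. Terminal ``*`` is stripped; B/Z/U/O fold to X.

    The header token before the first whitespace becomes the id, the
    remainder the description. Duplicate ids and illegal residues are
    rejected with informative errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    header: tuple[str, str] | None = None
    chunks: list[str] = []
    chunk_lines: list[int] = []

    def flush() -> None:
        nonlocal header, chunks, chunk_lines
        if header is None:
            return
        rid, desc = header
        pieces = []
        for text, ln in zip(chunks, chunk_lines):
            pieces.append(normalize_sequence(text, line=ln))
        seq = "".join(pieces)
        # a terminal '*' split across lines is already handled per-line;
        # normalize once more over the joined sequence for safety
        records.append(ProteinRecord(id=rid, sequence=seq, description=desc))
        header, chunks, chunk_lines = None, [], []

    with open(path, encoding="utf-8", newline=None) as fh:
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(maxsplit=1)
                if not parts:
                    raise FastaParseError("empty FASTA header", line=lineno)
                rid = parts[0]
                if rid in seen:
                    raise DuplicateIdError(f"duplicate record id {rid!r}")
                seen.add(rid)
                header = (rid, parts[1].strip() if len(parts) > 1 else "")
            else:
                if header is None:
                    raise FastaParseError(
                        "sequence data before first '>' header", line=lineno
                    )
                chunks.append(line)
                chunk_lines.append(lineno)
    flush()
    if not records:
        raise EmptyInputError(f"no FASTA records in {path}")
    return records


def write_fasta(records, path, wrap_width: int = 60) -> None:
    """Write records as FASTA; round-trips through :func:`read_fasta`."""
    if wrap_width < 1:
        raise ValueError("wrap_width must be >= 1")
    with open(path, "w", encoding="utf-8") as fh:
        for rec in records:
            head = f">{rec.id}"
            if rec.description:
                head += f" {rec.description}"
            fh.write(head + "\n")
            seq = rec.sequence
            for i in range(0, len(seq), wrap_width):
                fh.write(seq[i : i + wrap_width] + "\n")


def read_stockholm(path) -> Msa:
    """Read a Stockholm 1.0 seed alignment ('.' and '-' both become '-')."""
    try:
        aln = AlignIO.read(path, "stockholm")
    except ValueError as exc:
        msg = str(exc).lower()
        if "length" in msg or "same length" in msg:
            raise AlignmentShapeError(str(exc)) from exc
        raise EmptyInputError(f"no Stockholm alignment in {path}: {exc}") from exc
    rows = []
    for seqrec in aln:
        row = normalize_sequence(str(seqrec.seq), keep_gaps=True)
        rows.append((seqrec.id, row))
    if not rows:
        raise EmptyInputError(f"no sequence rows in {path}")
    return Msa(records=rows)


def read_aligned_fasta(path) -> Msa:
    """Read an aligned FASTA file (gapped rows of equal length) as an Msa."""
    rows = []
    with open(path, encoding="utf-8", newline=None) as fh:
        rid = None
        chunks: list[str] = []
        for lineno, rawline in enumerate(fh, start=1):
            line = rawline.rstrip("\r\n")
            if not line.strip():
                continue
            if line.startswith(">"):
                if rid is not None:
                    rows.append((rid, "".join(chunks)))
                rid = line[1:].split(maxsplit=1)[0] if line[1:].strip() else None
                if rid is None:
                    raise FastaParseError("empty FASTA header", line=lineno)
                chunks = []
            else:
                if rid is None:
                    raise FastaParseError(
                        "sequence data before first '>' header", line=lineno
                    )
                chunks.append(normalize_sequence(line, line=lineno, keep_gaps=True))
        if rid is not None:
            rows.append((rid, "".join(chunks)))
    if not rows:
        raise EmptyInputError(f"no FASTA records in {path}")
    return Msa(records=rows)


def write_aligned_fasta(msa: Msa, path, wrap_width: int = 60) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rid, row in msa.records:
            fh.write(f">{rid}\n")
            for i in range(0, len(row), wrap_width):
                fh.write(row[i : i + wrap_width] + "\n")


def read_table(path, required_columns=()) -> pd.DataFrame:
    """Read a TSV with a header row; error names any missing column."""
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError as exc:
        raise EmptyInputError(f"empty table {path}") from exc
    missing = [c for c in required_columns if c not in df.columns]
    if missing:
        raise SchemaError(f"table {path} is missing columns: {', '.join(missing)}")
    return df


def write_table(df: pd.DataFrame, path) -> None:
    """Write a TSV with header; round-trips through :func:`read_table`."""
    df.to_csv(path, sep="\t", index=False)
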