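"""Global pairwise alignment, percent identity, and coordinate transfer.

The positional validation of the screening funnel needs exactly one
alignment primitive: an optimal global alignment of a candidate against
the reference enzyme, from which reference active-site coordinates
(Tyr114–Cys116, Lys240–Asp241) are mapped into candidate coordinates.
Alignment itself is Gotoh affine-gap Needleman–Wunsch via Biopython's
``PairwiseAligner``; a gap run of length L costs ``gap_open +
(L-1) * gap_extend``, echoing the Kalign penalties (10.0 open, 3.0
extend) used for the published alignment.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import AlphabetError, EmptyInputError
from .io import Msa, ProteinRecord

#: Marker for a reference position that lands on a gap in the candidate.
GAP = None

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def default_matrix():
    """BLOSUM62 (includes X/B/Z columns)."""
    return _BLOSUM62


def simple_matrix(match: float = 1.0, mismatch: float = -1.0,
                  alphabet: str = "ACDEFGHIKLMNPQRSTVWYX"):
    """Match/mismatch matrix over the protein alphabet (for tests/oracles)."""
    arr = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            arr[a, b] = match if a == b else mismatch
    return arr


@dataclass
class AlignmentResult:
    """A scored global alignment of ``a`` against ``b`` with a column map."""

    aligned_a: str
    aligned_b: str
    score: float
    identity_pct: float
    #: entry i-1 is the 1-based b-position matched to a-position i, or GAP.
    column_map: list

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b):
            raise ValueError("aligned strings differ in length")


def _identity(aligned_a: str, aligned_b: str, denominator: str = "columns") -> float:
    """Percent identity to two decimals.

    ``denominator="columns"`` divides by total alignment columns
    (BLAST-style); ``"shorter"`` divides by the shorter input length.
    """
    ident = sum(
        1 for x, y in zip(aligned_a, aligned_b) if x == y and x != "-"
    )
    if denominator == "columns":
        denom = len(aligned_a)
    elif denominator == "shorter":
        denom = min(
            len(aligned_a.replace("-", "")), len(aligned_b.replace("-", ""))
        )
    else:
        raise ValueError(f"unknown identity denominator {denominator!r}")
    return round(100.0 * ident / denom, 2)


def global_align(
    a: str,
    b: str,
    substitution_matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 3.0,
    identity_denominator: str = "columns",
) -> AlignmentResult:
    """Optimal global affine-gap alignment of ``a`` and ``b``.

    End gaps are penalized (true global mode). Raises
    :class:`EmptyInputError` for empty sequences and
    :class:`AlphabetError` for residues the matrix does not cover.
    """
    if not a or not b:
        raise EmptyInputError("cannot align an empty sequence")
    matrix = substitution_matrix if substitution_matrix is not None else _BLOSUM62
    allowed = set(str(matrix.alphabet))
    bad = (set(a) | set(b)) - allowed
    if bad:
        raise AlphabetError(
            f"residues {sorted(bad)} absent from substitution matrix"
        )
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = matrix
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    aln = aligner.align(a, b)[0]
    aligned_a, aligned_b = str(aln[0]), str(aln[1])

    column_map: list = []
    pos_b = 0
    for ca, cb in zip(aligned_a, aligned_b):
        if cb != "-":
            pos_b += 1
        if ca != "-":
            column_map.append(pos_b if cb != "-" else GAP)
    return AlignmentResult(
        aligned_a=aligned_a,
        aligned_b=aligned_b,
        score=float(aln.score),
        identity_pct=_identity(aligned_a, aligned_b, identity_denominator),
        column_map=column_map,
    )


def percent_identity(result: AlignmentResult, denominator: str = "columns") -> float:
    """Recompute percent identity of an alignment (two decimals)."""
    return _identity(result.aligned_a, result.aligned_b, denominator)


def map_position(result: AlignmentResult, pos_in_a: int):
    """Map a 1-based position of ``a`` to its matched position in ``b``.

    Returns :data:`GAP` when ``b`` has a gap in that column.
    """
    if not 1 <= pos_in_a <= len(result.column_map):
        raise IndexError(
            f"position {pos_in_a} outside 1..{len(result.column_map)}"
        )
    return result.column_map[pos_in_a - 1]


def reference_anchored_msa(
    reference: ProteinRecord,
    records,
    substitution_matrix=None,
    gap_open: float = 10.0,
    gap_extend: float = 3.0,
) -> Msa:
    """Star multiple alignment of ``records`` around ``reference``.

    Each record is globally aligned to the reference; rows are merged on
    reference columns ("once a gap, always a gap"): the insert length in
    each inter-reference slot is the maximum over records. The reference
    row comes first. This preserves candidate↔reference coordinate
    transfer exactly, which is all the positional validation needs.
    """
    records = list(records)
    if not records:
        raise EmptyInputError("no records to align")
    ref = reference.sequence
    n_slots = len(ref) + 1  # slot i holds inserts before ref position i+1

    per_record = []  # (id, slots) where slots[i] = residues inserted in slot i
    for rec in records:
        res = global_align(
            ref,
            rec.sequence,
            substitution_matrix=substitution_matrix,
            gap_open=gap_open,
            gap_extend=gap_extend,
        )
        slots = [[] for _ in range(n_slots)]
        matched = [None] * len(ref)  # residue of rec aligned to ref pos, or None
        ref_i = 0
        for ca, cb in zip(res.aligned_a, res.aligned_b):
            if ca == "-":
                slots[ref_i].append(cb)
            else:
                if cb != "-":
                    matched[ref_i] = cb
                ref_i += 1
        per_record.append((rec.id, slots, matched))

    max_ins = [0] * n_slots
    for _, slots, _ in per_record:
        for i, s in enumerate(slots):
            max_ins[i] = max(max_ins[i], len(s))

    ref_row = []
    for i in range(len(ref)):
        ref_row.append("-" * max_ins[i] + ref[i])
    ref_row.append("-" * max_ins[len(ref)])
    rows = [(reference.id, "".join(ref_row))]
    for rid, slots, matched in per_record:
        row = []
        for i in range(len(ref)):
            ins = "".join(slots[i])
            row.append(ins + "-" * (max_ins[i] - len(ins)))
            row.append(matched[i] if matched[i] is not None else "-")
        ins = "".join(slots[len(ref)])
        row.append(ins + "-" * (max_ins[len(ref)] - len(ins)))
        rows.append((rid, "".join(row)))
    return Msa(records=rows)
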