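"""Catalytic-residue anchor filter for methioninase candidates.

True methionine gamma-lyases carry two short conserved stretches in the
active site: Tyr-Gly-Cys ("YGC", positions 114-116 in the Pseudomonas
putida enzyme) and Lys-Asp ("KD", positions 240-241). Close homologs
such as cystathionine gamma-synthase are captured by the same family
model but lack one of the stretches, or carry it at a different
position. The filter is staged exactly like the published funnel:

1. optional family-model capture (records below the bit-score threshold
   stop at ``NO_HMM_HIT``);
2. optional annotation consensus (records whose external annotation is
   not an accepted label stop at ``REJECTED_ANNOTATION``);
3. YGC present anywhere in the candidate, else ``NO_YGC``;
4. KD present anywhere, else ``NO_KD``;
5. both motifs must sit at the candidate positions onto which the
   reference anchor coordinates map under a global alignment —
   ``CONFIRMED``, otherwise ``MISPLACED``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import pandas as pd

from . import pairwise
from .errors import AnchorInconsistencyError, MglError, SchemaError
from .io import ProteinRecord


class Status(str, enum.Enum):
    NO_HMM_HIT = "NO_HMM_HIT"
    REJECTED_ANNOTATION = "REJECTED_ANNOTATION"
    NO_YGC = "NO_YGC"
    NO_KD = "NO_KD"
    MISPLACED = "MISPLACED"
    CONFIRMED = "CONFIRMED"


@dataclass
class ReferenceAnchor:
    """Reference enzyme plus the 1-based anchor coordinates of both motifs."""

    reference: ProteinRecord
    motif1: str = "YGC"
    motif1_start: int = 114
    motif2: str = "KD"
    motif2_start: int = 240

    def __post_init__(self) -> None:
        if not self.motif1 or not self.motif2:
            raise AnchorInconsistencyError("anchor motifs must be non-empty")
        if self.motif1_start < 1 or self.motif2_start < 1:
            raise AnchorInconsistencyError("anchor positions are 1-based (>= 1)")
        seq = self.reference.sequence
        for motif, start in ((self.motif1, self.motif1_start),
                             (self.motif2, self.motif2_start)):
            got = seq[start - 1 : start - 1 + len(motif)]
            if got != motif:
                raise AnchorInconsistencyError(
                    f"reference {self.reference.id!r} carries {got!r} at "
                    f"position {start}, expected {motif!r}"
                )


@dataclass
class ScreenVerdict:
    """Staged classification of one candidate with supporting positions."""

    id: str
    status: Status
    motif1_positions: list[int] = field(default_factory=list)
    motif2_positions: list[int] = field(default_factory=list)
    anchor_mapped_1: int | None = None
    anchor_mapped_2: int | None = None
    bit_score: float | None = None


@dataclass
class FunnelCounts:
    """Candidate counts surviving each stage of the screen."""

    n_input: int
    n_hmm_pass: int
    n_with_ygc: int
    n_with_ygc_kd: int
    n_confirmed: int

    def __post_init__(self) -> None:
        chain = (
            self.n_input,
            self.n_hmm_pass,
            self.n_with_ygc,
            self.n_with_ygc_kd,
            self.n_confirmed,
        )
        if any(a < b for a, b in zip(chain, chain[1:])):
            raise MglError(f"funnel counts not monotone: {chain}")


def find_motifs(sequence: str, motif: str) -> list[int]:
    """All (possibly overlapping) 1-based start positions of ``motif``."""
    if not motif:
        raise ValueError("motif must be non-empty")
    out = []
    start = sequence.find(motif)
    while start != -1:
        out.append(start + 1)
        start = sequence.find(motif, start + 1)
    return out


def _motif_at_anchor(
    candidate_seq: str,
    result: pairwise.AlignmentResult,
    motif: str,
    anchor_start: int,
    tolerance: int,
) -> tuple[bool, int | None]:
    """Check one motif against its reference-mapped candidate location.

    Requires every anchor column to map to a non-gap candidate position,
    those positions to be consecutive (an insertion inside the motif
    rejects), and the candidate residues there to spell the motif,
    optionally allowing a start offset of up to ``tolerance`` columns.
    Returns (ok, mapped start or None).
    """
    mapped = [
        pairwise.map_position(result, anchor_start + j) for j in range(len(motif))
    ]
    if any(p is pairwise.GAP for p in mapped):
        return False, None
    start = mapped[0]
    if mapped != list(range(start, start + len(motif))):
        return False, start
    for d in range(-tolerance, tolerance + 1):
        s = start + d
        if s >= 1 and candidate_seq[s - 1 : s - 1 + len(motif)] == motif:
            return True, s
    return False, start


def classify(
    candidate: ProteinRecord,
    anchor: ReferenceAnchor,
    align_params: dict | None = None,
    position_tolerance: int = 0,
    bit_score: float | None = None,
) -> ScreenVerdict:
    """Run the motif-presence and positional stages on one candidate."""
    align_params = dict(align_params or {})
    seq = candidate.sequence
    m1 = find_motifs(seq, anchor.motif1)
    if not m1:
        return ScreenVerdict(candidate.id, Status.NO_YGC, bit_score=bit_score)
    m2 = find_motifs(seq, anchor.motif2)
    if not m2:
        return ScreenVerdict(
            candidate.id, Status.NO_KD, motif1_positions=m1, bit_score=bit_score
        )
    result = pairwise.global_align(anchor.reference.sequence, seq, **align_params)
    ok1, mapped1 = _motif_at_anchor(
        seq, result, anchor.motif1, anchor.motif1_start, position_tolerance
    )
    ok2, mapped2 = _motif_at_anchor(
        seq, result, anchor.motif2, anchor.motif2_start, position_tolerance
    )
    status = Status.CONFIRMED if (ok1 and ok2) else Status.MISPLACED
    return ScreenVerdict(
        id=candidate.id,
        status=status,
        motif1_positions=m1,
        motif2_positions=m2,
        anchor_mapped_1=mapped1,
        anchor_mapped_2=mapped2,
        bit_score=bit_score,
    )


def screen_batch(
    records,
    anchor: ReferenceAnchor,
    align_params: dict | None = None,
    hmm_hits=None,
    annotation_table: pd.DataFrame | None = None,
    accepted_labels=frozenset({"methionine-gamma-lyase"}),
    position_tolerance: int = 0,
) -> tuple[list[ScreenVerdict], FunnelCounts]:
    """Classify every record and report the stage-by-stage funnel.

    ``hmm_hits`` (a list of HmmHit or an id->HmmHit mapping) gates the
    motif stages; records failing the model threshold stop at
    ``NO_HMM_HIT``. ``annotation_table`` (columns ``id``, ``label``)
    demotes records whose label is not accepted before the motif stages;
    ids absent from the table pass through (permissive default).
    """
    records = list(records)
    if hmm_hits is not None and not isinstance(hmm_hits, dict):
        hmm_hits = {h.id: h for h in hmm_hits}
    rejected: dict[str, str] = {}
    if annotation_table is not None and len(annotation_table):
        if not {"id", "label"}.issubset(annotation_table.columns):
            raise SchemaError("annotation table needs columns: id, label")
        for _, row in annotation_table.iterrows():
            if row["label"] not in accepted_labels:
                rejected[row["id"]] = row["label"]

    verdicts: list[ScreenVerdict] = []
    for rec in records:
        score = None
        if hmm_hits is not None:
            hit = hmm_hits.get(rec.id)
            score = hit.bit_score if hit else None
            if hit is None or not hit.passed:
                verdicts.append(
                    ScreenVerdict(rec.id, Status.NO_HMM_HIT, bit_score=score)
                )
                continue
        if rec.id in rejected:
            verdicts.append(
                ScreenVerdict(rec.id, Status.REJECTED_ANNOTATION, bit_score=score)
            )
            continue
        verdicts.append(
            classify(
                rec,
                anchor,
                align_params=align_params,
                position_tolerance=position_tolerance,
                bit_score=score,
            )
        )

    past_hmm = {
        Status.REJECTED_ANNOTATION,
        Status.NO_YGC,
        Status.NO_KD,
        Status.MISPLACED,
        Status.CONFIRMED,
    }
    with_ygc = {Status.NO_KD, Status.MISPLACED, Status.CONFIRMED}
    with_both = {Status.MISPLACED, Status.CONFIRMED}
    funnel = FunnelCounts(
        n_input=len(records),
        n_hmm_pass=sum(v.status in past_hmm for v in verdicts),
        n_with_ygc=sum(v.status in with_ygc for v in verdicts),
        n_with_ygc_kd=sum(v.status in with_both for v in verdicts),
        n_confirmed=sum(v.status is Status.CONFIRMED for v in verdicts),
    )
    return verdicts, funnel


def apply_annotation_filter(
    verdicts,
    annotation_table: pd.DataFrame,
    accepted_labels=frozenset({"methionine-gamma-lyase"}),
) -> list[ScreenVerdict]:
    """Demote verdicts whose external annotation is not an accepted label.

    Emulates the published consensus step in which candidates kept by the
    family model but annotated as a different enzyme were discarded. Ids
    absent from the table are left untouched.
    """
    if annotation_table is None:
        return list(verdicts)
    if len(annotation_table) and not {"id", "label"}.issubset(
        annotation_table.columns
    ):
        raise SchemaError("annotation table needs columns: id, label")
    labels = (
        dict(zip(annotation_table["id"], annotation_table["label"]))
        if len(annotation_table)
        else {}
    )
    out = []
    for v in verdicts:
        label = labels.get(v.id)
        if label is not None and label not in accepted_labels:
            out.append(
                ScreenVerdict(v.id, Status.REJECTED_ANNOTATION, bit_score=v.bit_score)
            )
        else:
            out.append(v)
    return out


def verdicts_to_table(verdicts) -> pd.DataFrame:
    """Verdicts as a TSV-ready table (positions joined with commas)."""
    rows = []
    for v in verdicts:
        rows.append(
            {
                "id": v.id,
                "status": v.status.value,
                "bit_score": "" if v.bit_score is None else f"{v.bit_score:.4f}",
                "motif1_positions": ",".join(map(str, v.motif1_positions)),
                "motif2_positions": ",".join(map(str, v.motif2_positions)),
                "anchor_mapped_1": "" if v.anchor_mapped_1 is None else v.anchor_mapped_1,
                "anchor_mapped_2": "" if v.anchor_mapped_2 is None else v.anchor_mapped_2,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "id",
            "status",
            "bit_score",
            "motif1_positions",
            "motif2_positions",
            "anchor_mapped_1",
            "anchor_mapped_2",
        ],
    )


def table_to_verdicts(df: pd.DataFrame) -> list[ScreenVerdict]:
    """Rebuild minimal verdicts (id + status) from a verdict table."""
    if not {"id", "status"}.issubset(df.columns):
        raise SchemaError("verdict table needs columns: id, status")
    out = []
    for _, row in df.iterrows():
        out.append(ScreenVerdict(id=row["id"], status=Status(row["status"])))
    return out
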