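"""Synthetic screening sets with known truth labels.

Real inputs to the funnel are predicted ORFs from genome assemblies and
metagenomes. For testing, this module emulates the mixture the screen
has to resolve:

* ``true_mgl`` — mutants of a reference methioninase whose anchor
  residues (YGC at 114, KD at 240 by default) are protected;
* ``decoy_no_ygc`` — the classic loss-of-function construction, the
  active-site Cys mutated to His, destroying the YGC stretch (the
  cystathionine-gamma-synthase-like false positive);
* ``decoy_no_kd`` — the anchor Lys mutated to Ala;
* ``decoy_misplaced`` — YGC excised at the anchor and re-inserted at
  least 30 residues away (KD intact), so only the positional stage can
  reject it;
* ``background`` — unrelated i.i.d. proteins of length 300-500.

Every record carries a GTDB-style lineage drawn from a weighted phylum
list whose default weights follow the published phylum shares of
confirmed methioninases (Proteobacteria 50 %, Firmicutes 29 %,
Firmicutes_A 13 %, remainder Fusobacteriota).

The generator does not model sequencing error, assembly artifacts, or
real family divergence profiles; see docs/methods.md for what that
implies about test coverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .anchors import ReferenceAnchor
from .errors import EmptyInputError, MglError
from .io import AMINO_ACIDS, ProteinRecord

#: Default lineages and sampling weights (phylum shares as published).
DEFAULT_PHYLA: list[tuple[str, float]] = [
    (
        "d__Bacteria;p__Proteobacteria;c__Gammaproteobacteria;o__Pseudomonadales;"
        "f__Porticoccaceae;g__HTCC2207;s__HTCC2207 sp002382445",
        0.50,
    ),
    (
        "d__Bacteria;p__Firmicutes;c__Bacilli;o__Bacillales;"
        "f__Bacillaceae;g__Bacillus;s__Bacillus synthetica",
        0.29,
    ),
    (
        "d__Bacteria;p__Firmicutes_A;c__Clostridia;o__Clostridiales;"
        "f__Clostridiaceae;g__Clostridium;s__Clostridium synthetica",
        0.13,
    ),
    (
        "d__Bacteria;p__Fusobacteriota;c__Fusobacteriia;o__Fusobacteriales;"
        "f__Fusobacteriaceae;g__Fusobacterium;s__Fusobacterium synthetica",
        0.08,
    ),
]

DECOY_KINDS = ("no_ygc", "no_kd", "misplaced", "background")

_UNIFORM_BG = np.full(20, 1.0 / 20.0)

#: Average residue composition of known proteins (Swiss-Prot-style
#: frequencies, ACDEFGHIKLMNPQRSTVWY order); used for the synthetic
#: reference so its length/mass relationship is realistic.
NATURAL_FREQS = np.array(
    [
        0.0825, 0.0137, 0.0545, 0.0675, 0.0386, 0.0707, 0.0227, 0.0596,
        0.0584, 0.0966, 0.0242, 0.0406, 0.0470, 0.0393, 0.0553, 0.0656,
        0.0534, 0.0687, 0.0108, 0.0292,
    ]
)
NATURAL_FREQS = NATURAL_FREQS / NATURAL_FREQS.sum()


@dataclass
class SynthConfig:
    """Class counts, mutation rate, lineage weights, and the RNG seed."""

    n_true: int = 5
    n_no_ygc: int = 5
    n_no_kd: int = 5
    n_misplaced: int = 5
    n_background: int = 5
    mutation_rate: float = 0.02
    seed: int = 0
    phyla: list[tuple[str, float]] = field(
        default_factory=lambda: list(DEFAULT_PHYLA)
    )
    background_freqs: np.ndarray = field(
        default_factory=lambda: _UNIFORM_BG.copy()
    )

    def __post_init__(self) -> None:
        counts = (
            self.n_true,
            self.n_no_ygc,
            self.n_no_kd,
            self.n_misplaced,
            self.n_background,
        )
        if any(c < 0 for c in counts):
            raise MglError("class counts must be >= 0")
        if not 0.0 <= self.mutation_rate <= 1.0:
            raise MglError("mutation_rate must be in [0, 1]")
        if not self.phyla or sum(w for _, w in self.phyla) <= 0:
            raise MglError("phylum weights must sum to a positive number")
        self.background_freqs = np.asarray(self.background_freqs, dtype=float)
        if self.background_freqs.shape != (20,) or not np.isclose(
            self.background_freqs.sum(), 1.0
        ):
            raise MglError("background_freqs must be a 20-vector summing to 1")


def make_synthetic_reference(
    length: int = 398,
    motif1: str = "YGC",
    motif1_start: int = 114,
    motif2: str = "KD",
    motif2_start: int = 240,
    seed: int = 2024,
) -> tuple[ProteinRecord, ReferenceAnchor]:
    """A synthetic stand-in reference methioninase.

    Random composition with the two anchor motifs planted at the
    P. putida coordinates; the default length (398 residues) matches a
    typical bacterial methionine gamma-lyase monomer. This is a
    synthetic test object, not the real P. putida sequence — to screen
    against the real enzyme, load it from FASTA and build a
    :class:`~mglscreen.anchors.ReferenceAnchor` from it.
    """
    rng = np.random.default_rng(seed)
    seq = list(rng.choice(list(AMINO_ACIDS), size=length, p=NATURAL_FREQS))
    protected: set[int] = set()
    for motif, start in ((motif1, motif1_start), (motif2, motif2_start)):
        if start - 1 + len(motif) > length:
            raise MglError("anchor motif does not fit in the requested length")
        seq[start - 1 : start - 1 + len(motif)] = list(motif)
        protected.update(range(start - 1, start - 1 + len(motif)))
    # anchors are the *only* motif occurrences: accidental copies elsewhere
    # would blur the truth labels of the decoy classes built from this
    for motif in (motif1, motif2):
        _scrub_motif(seq, motif, rng, protected)
    record = ProteinRecord(
        id="MGL_reference_synthetic",
        sequence="".join(seq),
        description="synthetic stand-in reference methioninase",
    )
    anchor = ReferenceAnchor(
        reference=record,
        motif1=motif1,
        motif1_start=motif1_start,
        motif2=motif2,
        motif2_start=motif2_start,
    )
    return record, anchor


def _scrub_motif(
    seq: list[str], motif: str, rng: np.random.Generator, protected: set[int]
) -> None:
    """Remove every occurrence of ``motif`` outside ``protected`` (in place).

    One residue of each occurrence is resampled until no occurrence
    remains; protected positions are never touched (motif letters are
    disjoint between YGC and KD, so occurrences never straddle the other
    anchor).
    """
    text = "".join(seq)
    guard = 0
    while True:
        hits = [
            p
            for p in range(len(text) - len(motif) + 1)
            if text[p : p + len(motif)] == motif
            and not set(range(p, p + len(motif))) <= protected
        ]
        if not hits:
            return
        guard += 1
        if guard > 100 * len(seq):
            raise MglError("could not scrub motif occurrences")
        for p in hits:
            targets = [q for q in range(p, p + len(motif)) if q not in protected]
            q = targets[len(targets) // 2]
            old = seq[q]
            choices = [a for a in AMINO_ACIDS if a != old and a not in motif]
            seq[q] = str(rng.choice(choices))
        text = "".join(seq)


def _anchor_positions(anchor: ReferenceAnchor) -> set[int]:
    """0-based protected positions (both motifs)."""
    pos = set()
    for motif, start in (
        (anchor.motif1, anchor.motif1_start),
        (anchor.motif2, anchor.motif2_start),
    ):
        pos.update(range(start - 1, start - 1 + len(motif)))
    return pos


def _mutate_family(
    reference: ProteinRecord,
    anchor: ReferenceAnchor,
    n: int,
    mutation_rate: float,
    rng: np.random.Generator,
) -> list[list[str]]:
    """n mutant sequences (as residue lists); anchor positions untouched."""
    if reference.sequence != anchor.reference.sequence:
        # the anchor must describe this reference
        ReferenceAnchor(
            reference=reference,
            motif1=anchor.motif1,
            motif1_start=anchor.motif1_start,
            motif2=anchor.motif2,
            motif2_start=anchor.motif2_start,
        )
    protected = _anchor_positions(anchor)
    base = np.array([AMINO_ACIDS.index(c) if c != "X" else -1
                     for c in reference.sequence])
    L = len(base)
    mask_protect = np.zeros(L, dtype=bool)
    mask_protect[sorted(protected)] = True
    out = []
    for _ in range(n):
        mutate = rng.random(L) < mutation_rate
        mutate &= ~mask_protect
        mutate &= base >= 0  # leave X alone
        offsets = rng.integers(1, 20, size=L)
        newidx = np.where(mutate, (base + offsets) % 20, base)
        out.append(
            [AMINO_ACIDS[i] if i >= 0 else "X" for i in newidx]
        )
    return out


def generate_family(
    reference: ProteinRecord,
    anchors: ReferenceAnchor,
    n: int,
    mutation_rate: float,
    seed: int,
) -> list[ProteinRecord]:
    """Anchor-consistent mutants of the reference (truth label ``true_mgl``).

    Each non-anchor position is substituted with probability
    ``mutation_rate`` to a uniformly drawn different residue;
    deterministic given ``seed``.
    """
    if n < 0:
        raise MglError("n must be >= 0")
    rng = np.random.default_rng(seed)
    seqs = _mutate_family(reference, anchors, n, mutation_rate, rng)
    return [
        ProteinRecord(
            id=f"true_mgl_{i:04d}",
            sequence="".join(s),
            truth_label="true_mgl",
        )
        for i, s in enumerate(seqs)
    ]


def generate_decoys(
    reference: ProteinRecord,
    anchors: ReferenceAnchor,
    kind: str,
    n: int,
    mutation_rate: float,
    seed: int,
    background_freqs: np.ndarray | None = None,
) -> list[ProteinRecord]:
    """Decoys of one class (see module docstring for the constructions)."""
    if kind not in DECOY_KINDS:
        raise MglError(f"unknown decoy kind {kind!r}; one of {DECOY_KINDS}")
    if n < 0:
        raise MglError("n must be >= 0")
    rng = np.random.default_rng(seed)

    if kind == "background":
        freqs = (
            np.asarray(background_freqs, dtype=float)
            if background_freqs is not None
            else _UNIFORM_BG
        )
        if freqs.shape != (20,) or not np.isclose(freqs.sum(), 1.0):
            raise MglError("background_freqs must be a 20-vector summing to 1")
        out = []
        for i in range(n):
            L = int(rng.integers(300, 501))
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=L, p=freqs))
            out.append(
                ProteinRecord(
                    id=f"background_{i:04d}", sequence=seq, truth_label="background"
                )
            )
        return out

    seqs = _mutate_family(reference, anchors, n, mutation_rate, rng)
    m1 = anchors.motif1_start - 1  # 0-based YGC start
    cys = m1 + len(anchors.motif1) - 1
    lys = anchors.motif2_start - 1
    out = []
    kd_anchor = set(range(lys, lys + len(anchors.motif2)))
    ygc_anchor = set(range(m1, m1 + len(anchors.motif1)))
    for i, s in enumerate(seqs):
        if kind == "no_ygc":
            s[cys] = "H"  # Cys116 -> His, the classic inactivating mutation
            # absence anywhere is the class definition: clear accidental
            # copies (mutation can create them)
            _scrub_motif(s, anchors.motif1, rng, kd_anchor)
            label = "decoy_no_ygc"
        elif kind == "no_kd":
            s[lys] = "A"
            _scrub_motif(s, anchors.motif2, rng, ygc_anchor)
            label = "decoy_no_kd"
        else:  # misplaced
            motif = anchors.motif1
            del s[m1 : m1 + len(motif)]
            kd0 = anchors.motif2_start - 1
            if kd0 > m1:
                kd0 -= len(motif)
            candidates = [
                p
                for p in range(len(s) + 1)
                if abs(p - m1) >= 30 and p != kd0 + 1  # keep KD contiguous
            ]
            p = int(rng.choice(candidates))
            s[p:p] = list(motif)
            label = "decoy_misplaced"
        out.append(
            ProteinRecord(
                id=f"decoy_{kind}_{i:04d}", sequence="".join(s), truth_label=label
            )
        )
    return out


#: The verdict status each engineered class must receive (motif stages
#: only). Background proteins are random: they may contain either motif
#: by chance, so their only guarantee is "never confirmed".
EXPECTED_STATUS = {
    "true_mgl": "CONFIRMED",
    "decoy_no_ygc": "NO_YGC",
    "decoy_no_kd": "NO_KD",
    "decoy_misplaced": "MISPLACED",
    "background": None,
}


def recovered(truth_label: str, status) -> bool:
    """Does a verdict status recover a record's truth label?

    Engineered classes must land on their exact funnel stage; background
    records are recovered by anything except CONFIRMED.
    """
    value = getattr(status, "value", status)
    expected = EXPECTED_STATUS[truth_label]
    if expected is None:
        return value != "CONFIRMED"
    return value == expected


def generate_screen_set(
    config: SynthConfig,
    reference: ProteinRecord,
    anchors: ReferenceAnchor,
) -> tuple[list[ProteinRecord], pd.DataFrame]:
    """A shuffled labelled screening set plus its truth table.

    Returns the records (each with an assigned lineage) and a DataFrame
    with columns ``id``, ``truth_label``, ``lineage``. Deterministic
    given ``config.seed``.
    """
    total = (
        config.n_true
        + config.n_no_ygc
        + config.n_no_kd
        + config.n_misplaced
        + config.n_background
    )
    if total == 0:
        raise EmptyInputError("all class counts are zero")
    children = np.random.SeedSequence(config.seed).spawn(6)
    seeds = [int(c.generate_state(1)[0] % (2**31)) for c in children]
    records: list[ProteinRecord] = []
    records += generate_family(
        reference, anchors, config.n_true, config.mutation_rate, seeds[0]
    )
    records += generate_decoys(
        reference, anchors, "no_ygc", config.n_no_ygc, config.mutation_rate, seeds[1]
    )
    records += generate_decoys(
        reference, anchors, "no_kd", config.n_no_kd, config.mutation_rate, seeds[2]
    )
    records += generate_decoys(
        reference,
        anchors,
        "misplaced",
        config.n_misplaced,
        config.mutation_rate,
        seeds[3],
    )
    records += generate_decoys(
        reference,
        anchors,
        "background",
        config.n_background,
        config.mutation_rate,
        seeds[4],
        background_freqs=config.background_freqs,
    )

    rng = np.random.default_rng(seeds[5])
    lineages = [lin for lin, _ in config.phyla]
    weights = np.array([w for _, w in config.phyla], dtype=float)
    weights /= weights.sum()
    for rec in records:
        rec.taxonomy = lineages[int(rng.choice(len(lineages), p=weights))]
    order = rng.permutation(len(records))
    records = [records[i] for i in order]
    truth = pd.DataFrame(
        {
            "id": [r.id for r in records],
            "truth_label": [r.truth_label for r in records],
            "lineage": [r.taxonomy for r in records],
        }
    )
    return records, truth


def background_is_motif_free(records, anchors: ReferenceAnchor) -> bool:
    """True when no background record contains the primary motif.

    The funnel fixture in the acceptance checks requires a background
    class free of accidental YGC occurrences; callers verify the seed
    they use with this predicate rather than altering the generator.
    """
    return not any(
        anchors.motif1 in r.sequence
        for r in records
        if r.truth_label == "background"
    )
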