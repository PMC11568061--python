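"""Profile hidden Markov models for homology capture.

A plan7-style profile (match/insert/delete states, seven transition
classes per node) is either built from a seed alignment or loaded from
a HMMER3 ASCII file (e.g. TIGRFAM's methionine gamma-lyase family
model). Candidates are scored in *global* mode: the bit score is the
log2-odds of the best (Viterbi) or summed (forward) state path emitting
the whole sequence against an i.i.d. background null. This differs from
hmmscan's multihit local mode, so score thresholds are calibrated on
the data at hand rather than copied across programs; the classic
threshold of 150 bits is kept as the package default for the capture
stage.

Transition columns follow the HMMER3 layout::

    0 M->M   1 M->I   2 M->D   3 I->M   4 I->I   5 D->M   6 D->D

Row k holds transitions out of node k; row 0 is the begin node (B acts
as M0, and D0 does not exist), row M feeds the end state (M->M there
means M->E).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateModelError, EmptyInputError, FormatError, MglError
from .io import AMINO_ACIDS, Msa

_AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
_NEG_INF = -np.inf

MM, MI, MD, IM, II, DM, DD = range(7)


@dataclass
class ProfileHMM:
    """Profile HMM with emission/transition probabilities and a null model."""

    match_emissions: np.ndarray  # (M, 20)
    insert_emissions: np.ndarray  # (M+1, 20)
    transitions: np.ndarray  # (M+1, 7)
    background: np.ndarray  # (20,)
    name: str = "profile"
    length: int = field(init=False)

    def __post_init__(self) -> None:
        self.match_emissions = np.asarray(self.match_emissions, dtype=float)
        self.insert_emissions = np.asarray(self.insert_emissions, dtype=float)
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        m = self.match_emissions.shape[0]
        if m < 1:
            raise DegenerateModelError("model must have at least one match state")
        if self.match_emissions.shape != (m, 20):
            raise MglError("match_emissions must be (M, 20)")
        if self.insert_emissions.shape != (m + 1, 20):
            raise MglError("insert_emissions must be (M+1, 20)")
        if self.transitions.shape != (m + 1, 7):
            raise MglError("transitions must be (M+1, 7)")
        self.length = m
        tol = 1e-6
        if not np.allclose(self.match_emissions.sum(axis=1), 1.0, atol=tol):
            raise MglError("match emission rows must sum to 1")
        if not np.allclose(self.insert_emissions.sum(axis=1), 1.0, atol=tol):
            raise MglError("insert emission rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=tol):
            raise MglError("background must sum to 1")
        t = self.transitions
        if not np.allclose(t[:, [MM, MI, MD]].sum(axis=1), 1.0, atol=tol):
            raise MglError("M-state transition rows must sum to 1")
        if not np.allclose(t[:, [IM, II]].sum(axis=1), 1.0, atol=tol):
            raise MglError("I-state transition rows must sum to 1")
        # D0 does not exist; rows 1..M must normalize.
        if m >= 1 and not np.allclose(t[1:, [DM, DD]].sum(axis=1), 1.0, atol=tol):
            raise MglError("D-state transition rows must sum to 1")
        if not np.isclose(t[m, MD], 0.0, atol=tol) or not np.isclose(
            t[m, DD], 0.0, atol=tol
        ):
            raise MglError("no delete state beyond the last node")

    def consensus(self) -> str:
        """Most probable residue of each match state."""
        return "".join(AMINO_ACIDS[i] for i in self.match_emissions.argmax(axis=1))


@dataclass
class HmmHit:
    """Bit score of one record against a profile, with the threshold verdict."""

    id: str
    bit_score: float
    passed: bool


def build_from_msa(
    msa: Msa, gap_fraction_cutoff: float = 0.5, pseudocount: float = 1.0
) -> ProfileHMM:
    """Estimate a profile from a seed alignment.

    Columns whose gap fraction is below ``gap_fraction_cutoff`` become
    match states. Emissions are Laplace-smoothed observed frequencies,
    ``P(a) = (count_a + pc) / (n_observed + 20 pc)``; transitions are
    counted along each row's implied state path and smoothed the same
    way (three outcomes from M, two from I and D). The null model is the
    smoothed overall residue frequency of the alignment. X residues are
    treated as missing data.
    """
    rows = [row for _, row in msa.records]
    n_rows = len(rows)
    ncol = msa.length
    cols = np.array([[c for c in row] for row in rows])
    gap_frac = (cols == "-").sum(axis=0) / n_rows
    is_match = gap_frac < gap_fraction_cutoff
    match_cols = np.nonzero(is_match)[0]
    m = len(match_cols)
    if m == 0:
        raise DegenerateModelError("no match columns at this gap cutoff")
    pc = float(pseudocount)

    def smooth(counts: np.ndarray) -> np.ndarray:
        return (counts + pc) / (counts.sum() + 20.0 * pc)

    # emissions
    match_counts = np.zeros((m, 20))
    insert_counts = np.zeros((m + 1, 20))
    node_of_col = np.zeros(ncol, dtype=int)  # insert node owning each column
    k = 0
    for j in range(ncol):
        if is_match[j]:
            k += 1
            node_of_col[j] = k  # match node number for match columns
        else:
            node_of_col[j] = k  # insert belongs to preceding match node
    bg_counts = np.zeros(20)
    for row in rows:
        for j, ch in enumerate(row):
            if ch in ("-", "X"):
                continue
            ai = _AA_INDEX[ch]
            bg_counts[ai] += 1
            if is_match[j]:
                match_counts[node_of_col[j] - 1, ai] += 1
            else:
                insert_counts[node_of_col[j], ai] += 1
    match_em = np.apply_along_axis(smooth, 1, match_counts)
    insert_em = np.apply_along_axis(smooth, 1, insert_counts)
    background = smooth(bg_counts)

    # transitions from per-row state paths
    tcounts = np.zeros((m + 1, 7))
    for row in rows:
        state, node = "M", 0  # begin acts as M0
        for j in range(ncol):
            ch = row[j]
            if is_match[j]:
                nxt = "M" if ch != "-" else "D"
                tcounts[node, _TIDX[(state, nxt)]] += 1
                state, node = nxt, node_of_col[j]
            else:
                if ch != "-":
                    tcounts[node, _TIDX[(state, "I")]] += 1
                    state = "I"
        tcounts[node, _TIDX[(state, "M")]] += 1  # exit to end state

    trans = np.zeros((m + 1, 7))
    for k in range(m + 1):
        last = k == m
        # from M: 3 outcomes (2 at the last node: no further delete)
        outs = [MM, MI] if last else [MM, MI, MD]
        tot = tcounts[k, outs].sum()
        for c in outs:
            trans[k, c] = (tcounts[k, c] + pc) / (tot + len(outs) * pc)
        # from I: 2 outcomes
        tot = tcounts[k, [IM, II]].sum()
        for c in (IM, II):
            trans[k, c] = (tcounts[k, c] + pc) / (tot + 2 * pc)
        # from D: 2 outcomes (forced exit at the last node); D0 absent
        if k == 0:
            trans[k, DM], trans[k, DD] = 1.0, 0.0
        elif last:
            trans[k, DM], trans[k, DD] = 1.0, 0.0
        else:
            tot = tcounts[k, [DM, DD]].sum()
            for c in (DM, DD):
                trans[k, c] = (tcounts[k, c] + pc) / (tot + 2 * pc)
    return ProfileHMM(
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=trans,
        background=background,
    )


_TIDX = {
    ("M", "M"): MM,
    ("M", "I"): MI,
    ("M", "D"): MD,
    ("I", "M"): IM,
    ("I", "I"): II,
    ("D", "M"): DM,
    ("D", "D"): DD,
}


def read_hmmer3_profile(path) -> ProfileHMM:
    """Load a HMMER3 ASCII profile (``HMMER3/f``) via pyhmmer.

    ``*`` emission fields become probability zero. The null model is the
    standard amino-acid background (HMMER3 files imply rather than store
    it). Non-HMMER3 magic raises :class:`FormatError`.
    """
    import pyhmmer

    try:
        with pyhmmer.plan7.HMMFile(str(path)) as hf:
            hmm = hf.read()
    except (ValueError, EOFError, OSError) as exc:
        raise FormatError(f"not a readable HMMER3 profile: {exc}") from exc
    if hmm is None:
        raise FormatError(f"no profile found in {path}")
    m = hmm.M
    match_em = np.array(hmm.match_emissions, dtype=float)[1:, :]
    insert_em = np.array(hmm.insert_emissions, dtype=float)
    trans = np.array(hmm.transition_probabilities, dtype=float)
    # numerical cleanup: renormalize rows (file stores rounded fields)
    match_em /= match_em.sum(axis=1, keepdims=True)
    insert_em /= insert_em.sum(axis=1, keepdims=True)
    t = trans.copy()
    t[:, [MM, MI, MD]] /= t[:, [MM, MI, MD]].sum(axis=1, keepdims=True)
    t[:, [IM, II]] /= t[:, [IM, II]].sum(axis=1, keepdims=True)
    dsum = t[1:, [DM, DD]].sum(axis=1, keepdims=True)
    t[1:, [DM, DD]] /= np.where(dsum > 0, dsum, 1.0)
    t[0, DM], t[0, DD] = 1.0, 0.0
    t[m, MD] = 0.0
    t[m, [MM, MI]] /= t[m, [MM, MI]].sum()
    t[m, DD] = 0.0
    t[m, DM] = 1.0
    bg = pyhmmer.plan7.Background(hmm.alphabet)
    background = np.array(bg.residue_frequencies, dtype=float)
    background /= background.sum()
    name = hmm.name.decode() if isinstance(hmm.name, bytes) else str(hmm.name)
    return ProfileHMM(
        match_emissions=match_em,
        insert_emissions=insert_em,
        transitions=t,
        background=background,
        name=name,
    )


def _log_odds_tables(hmm: ProfileHMM):
    with np.errstate(divide="ignore"):
        lbg = np.log2(hmm.background)
        lm = np.log2(hmm.match_emissions) - lbg  # (M, 20)
        li = np.log2(hmm.insert_emissions) - lbg  # (M+1, 20)
        lt = np.log2(hmm.transitions)  # (M+1, 7)
    return lm, li, lt


def _encode(sequence: str) -> list[int]:
    idx = []
    for ch in sequence:
        if ch == "X":
            idx.append(-1)
        elif ch in _AA_INDEX:
            idx.append(_AA_INDEX[ch])
        else:
            raise EmptyInputError(f"illegal residue {ch!r} in sequence")
    return idx


def _dp_score(hmm: ProfileHMM, sequence: str, mode: str) -> float:
    """Shared Viterbi/forward DP in log2-odds space (global mode).

    Delete states are non-emitting, so running the DP directly on
    log-odds emission terms equals scoring the raw path probability and
    subtracting the null model. An X residue contributes 0 bits at any
    emitting state.
    """
    if not sequence:
        raise EmptyInputError("cannot score an empty sequence")
    lm, li, lt = _log_odds_tables(hmm)
    m = hmm.length
    seq = _encode(sequence)
    L = len(seq)

    if mode == "viterbi":
        def combine(*vals):
            return max(vals)
        def combine_arr(a, b):
            return np.maximum(a, b)
    else:
        def combine(*vals):
            out = vals[0]
            for v in vals[1:]:
                out = np.logaddexp2(out, v)
            return float(out)
        def combine_arr(a, b):
            return np.logaddexp2(a, b)

    # vm[k], vi[k], vd[k] over nodes 0..M; node 0 "match" is the begin state.
    vm = np.full(m + 1, _NEG_INF)
    vi = np.full(m + 1, _NEG_INF)
    vd = np.full(m + 1, _NEG_INF)
    vm[0] = 0.0
    for k in range(1, m + 1):  # leading deletes
        src = combine(vm[k - 1] + lt[k - 1, MD], vd[k - 1] + lt[k - 1, DD])
        vd[k] = src

    for i in range(L):
        a = seq[i]
        em_m = lm[:, a] if a >= 0 else np.zeros(m)
        em_i = li[:, a] if a >= 0 else np.zeros(m + 1)
        new_m = np.full(m + 1, _NEG_INF)
        new_i = np.full(m + 1, _NEG_INF)
        new_d = np.full(m + 1, _NEG_INF)
        # match: from M/I/D of previous node, previous residue
        prev_m = vm[:-1] + lt[:-1, MM]
        prev_i = vi[:-1] + lt[:-1, IM]
        prev_d = vd[:-1] + lt[:-1, DM]
        best = combine_arr(combine_arr(prev_m, prev_i), prev_d)
        new_m[1:] = em_m + best
        # insert: from M/I of same node, previous residue
        new_i[:] = combine_arr(vm + lt[:, MI], vi + lt[:, II])
        new_i += em_i
        # delete chain within this residue column
        for k in range(1, m + 1):
            new_d[k] = combine(
                new_m[k - 1] + lt[k - 1, MD], new_d[k - 1] + lt[k - 1, DD]
            )
        vm, vi, vd = new_m, new_i, new_d

    final = combine(vm[m] + lt[m, MM], vi[m] + lt[m, IM], vd[m] + lt[m, DM])
    return float(final)


def viterbi_score(hmm: ProfileHMM, sequence: str) -> float:
    """Bit score of the single best global state path vs the null model."""
    return _dp_score(hmm, sequence, "viterbi")


def forward_score(hmm: ProfileHMM, sequence: str) -> float:
    """Bit score summed over all global state paths (always >= Viterbi)."""
    return _dp_score(hmm, sequence, "forward")


def screen(hmm: ProfileHMM, records, threshold: float = 150.0) -> list[HmmHit]:
    """Viterbi-score each record; ``passed`` marks scores >= threshold."""
    hits = []
    for rec in records:
        s = viterbi_score(hmm, rec.sequence)
        hits.append(HmmHit(id=rec.id, bit_score=s, passed=bool(s >= threshold)))
    return hits
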