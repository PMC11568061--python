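"""Independent oracles used by the test suite.

These deliberately avoid the code paths they check: path enumeration for
profile-HMM scores, exhaustive alignment enumeration for the global
aligner, and path-sum distance matrices from explicitly built trees for
neighbor joining.
"""

from __future__ import annotations

import numpy as np
from skbio import TreeNode

from mglscreen.io import AMINO_ACIDS
from mglscreen.profile_hmm import DD, DM, II, IM, MD, MI, MM, ProfileHMM


def random_small_model(rng: np.random.Generator, m: int) -> ProfileHMM:
    """A random valid profile with M match states (Dirichlet rows)."""
    me = rng.dirichlet(np.ones(20), size=m)
    ie = rng.dirichlet(np.ones(20), size=m + 1)
    t = np.zeros((m + 1, 7))
    for k in range(m + 1):
        t[k, [MM, MI, MD]] = rng.dirichlet(np.ones(3))
        t[k, [IM, II]] = rng.dirichlet(np.ones(2))
        t[k, [DM, DD]] = rng.dirichlet(np.ones(2))
    t[0, DM], t[0, DD] = 1.0, 0.0
    t[m, MD] = 0.0
    t[m, [MM, MI]] /= t[m, [MM, MI]].sum()
    t[m, DM], t[m, DD] = 1.0, 0.0
    bg = rng.dirichlet(np.ones(20))
    return ProfileHMM(me, ie, t, bg)


def enumerate_path_weights(hmm: ProfileHMM, seq: str) -> list[float]:
    """log2-odds weight of every complete global state path."""
    m = hmm.length
    idx = [AMINO_ACIDS.index(c) for c in seq]
    L = len(idx)
    with np.errstate(divide="ignore"):
        lbg = np.log2(hmm.background)
        lm = np.log2(hmm.match_emissions) - lbg
        li = np.log2(hmm.insert_emissions) - lbg
        lt = np.log2(hmm.transitions)
    out: list[float] = []

    def step(state: str, node: int, pos: int, w: float) -> None:
        if node == m and pos == L:
            col = {"M": MM, "I": IM, "D": DM}[state]
            out.append(w + lt[node, col])
        if node < m and pos < L:
            col = {"M": MM, "I": IM, "D": DM}[state]
            step("M", node + 1, pos + 1, w + lt[node, col] + lm[node, idx[pos]])
        if pos < L and state in ("M", "I"):
            col = {"M": MI, "I": II}[state]
            step("I", node, pos + 1, w + lt[node, col] + li[node, idx[pos]])
        if node < m and state in ("M", "D"):
            col = {"M": MD, "D": DD}[state]
            step("D", node + 1, pos, w + lt[node, col])

    step("M", 0, 0, 0.0)
    return out


def oracle_viterbi(hmm: ProfileHMM, seq: str) -> float:
    return max(enumerate_path_weights(hmm, seq))


def oracle_forward(hmm: ProfileHMM, seq: str) -> float:
    w = np.array(enumerate_path_weights(hmm, seq))
    return float(np.log2(np.exp2(w).sum()))


def brute_force_align_score(
    a: str,
    b: str,
    score_fn,
    gap_open: float,
    gap_extend: float,
) -> float:
    """Best global alignment score by exhaustive enumeration.

    A gap run of length L costs gap_open + (L-1) * gap_extend.
    """
    best = -np.inf

    def rec(i: int, j: int, prev: str, score: float) -> None:
        nonlocal best
        if i == len(a) and j == len(b):
            best = max(best, score)
            return
        if i < len(a) and j < len(b):
            rec(i + 1, j + 1, "M", score + score_fn(a[i], b[j]))
        if i < len(a):
            cost = gap_extend if prev == "A" else gap_open
            rec(i + 1, j, "A", score - cost)
        if j < len(b):
            cost = gap_extend if prev == "B" else gap_open
            rec(i, j + 1, "B", score - cost)

    rec(0, 0, "", 0.0)
    return float(best)


def random_additive_matrix(rng: np.random.Generator, n_taxa: int):
    """(labels, D) where D is the path-length matrix of a random binary tree."""
    nodes = [TreeNode(name=f"T{i}") for i in range(n_taxa)]
    for node in nodes:
        node.length = float(rng.uniform(0.1, 2.0))
    pool = list(nodes)
    while len(pool) > 2:
        i, j = sorted(rng.choice(len(pool), size=2, replace=False))
        a, b = pool[j], pool[i]
        parent = TreeNode(children=[a, b])
        parent.length = float(rng.uniform(0.1, 2.0))
        pool = [p for k, p in enumerate(pool) if k not in (i, j)] + [parent]
    root = TreeNode(children=pool)
    labels = [f"T{i}" for i in range(n_taxa)]
    tt = root.tip_tip_distances()
    d = np.zeros((n_taxa, n_taxa))
    for i, x in enumerate(labels):
        for j, y in enumerate(labels):
            if i != j:
                d[i, j] = tt[x, y]
    return labels, d
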