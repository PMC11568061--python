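import math

import numpy as np
import pytest

from mglscreen import synth
from mglscreen.errors import DegenerateModelError, EmptyInputError, FormatError
from mglscreen.io import AMINO_ACIDS, Msa
from mglscreen.profile_hmm import (
    DD,
    DM,
    II,
    IM,
    MD,
    MI,
    MM,
    ProfileHMM,
    build_from_msa,
    forward_score,
    read_hmmer3_profile,
    screen,
    viterbi_score,
)

from _oracles import oracle_forward, oracle_viterbi, random_small_model


def one_state_model(residue="A"):
    """Degenerate single-match-state model: P(residue)=1, uniform null."""
    me = np.zeros((1, 20))
    me[0, AMINO_ACIDS.index(residue)] = 1.0
    ie = np.full((2, 20), 1 / 20)
    t = np.zeros((2, 7))
    t[0] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]  # B -> M1 forced
    t[1] = [1.0, 0.0, 0.0, 1.0, 0.0, 1.0, 0.0]  # M1 -> E forced
    bg = np.full(20, 1 / 20)
    return ProfileHMM(me, ie, t, bg)


class TestBuildFromMsa:
    def test_laplace_smoothing_forced_example(self):
        msa = Msa(records=[("r1", "A"), ("r2", "A")])
        model = build_from_msa(msa, pseudocount=1.0)
        assert model.length == 1
        assert model.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(
            3 / 22
        )

    def test_majority_gap_column_excluded(self):
        msa = Msa(records=[("r1", "A-C"), ("r2", "A-C"), ("r3", "AGC")])
        model = build_from_msa(msa, gap_fraction_cutoff=0.5)
        assert model.length == 2

    def test_toy_alignment_match_column_count(self):
        rows = [
            ("r1", "MG-HKA"),
            ("r2", "MGAHKA"),
            ("r3", "MG-H-A"),
            ("r4", "MG-HKA"),
        ]
        # hand count: gap fractions per column 0,0,.75,0,.25,0 -> 5 match cols
        model = build_from_msa(Msa(records=rows), gap_fraction_cutoff=0.5)
        assert model.length == 5

    def test_all_gap_columns_degenerate(self):
        with pytest.raises(DegenerateModelError):
            # both columns are half gaps, at the 0.5 cutoff -> no match states
            build_from_msa(Msa(records=[("a", "A-"), ("b", "-A")]))

    def test_normalization_invariants(self, reference, anchor):
        from mglscreen import pairwise

        family = synth.generate_family(reference, anchor, 6, 0.05, seed=5)
        msa = pairwise.reference_anchored_msa(reference, family)
        model = build_from_msa(msa)
        assert np.allclose(model.match_emissions.sum(axis=1), 1.0)
        assert np.allclose(model.insert_emissions.sum(axis=1), 1.0)
        t = model.transitions
        assert np.allclose(t[:, [MM, MI, MD]].sum(axis=1), 1.0)
        assert np.allclose(t[:, [IM, II]].sum(axis=1), 1.0)
        assert np.allclose(t[1:, [DM, DD]].sum(axis=1), 1.0)


class TestScores:
    def test_degenerate_model_scores_log2_20(self):
        model = one_state_model("A")
        assert viterbi_score(model, "A") == pytest.approx(math.log2(20), abs=1e-9)
        # single path: forward equals viterbi
        assert forward_score(model, "A") == pytest.approx(
            viterbi_score(model, "A"), abs=1e-9
        )

    def test_empty_sequence_rejected(self):
        with pytest.raises(EmptyInputError):
            viterbi_score(one_state_model(), "")

    def test_consensus_scores_at_least_substituted_consensus(self, reference, anchor):
        from mglscreen import pairwise

        family = synth.generate_family(reference, anchor, 5, 0.03, seed=9)
        model = build_from_msa(pairwise.reference_anchored_msa(reference, family))
        cons = model.consensus()
        base = viterbi_score(model, cons)
        worst_letter = AMINO_ACIDS[int(model.match_emissions[50].argmin())]
        substituted = cons[:50] + worst_letter + cons[51:]
        assert base >= viterbi_score(model, substituted)

    @pytest.mark.parametrize("trial", range(20))
    def test_viterbi_and_forward_match_exhaustive_enumeration(self, trial):
        rng = np.random.default_rng(100 + trial)
        m = int(rng.integers(1, 4))
        L = int(rng.integers(1, 5))
        model = random_small_model(rng, m)
        seq = "".join(rng.choice(list(AMINO_ACIDS), size=L))
        assert viterbi_score(model, seq) == pytest.approx(
            oracle_viterbi(model, seq), abs=1e-9
        )
        assert forward_score(model, seq) == pytest.approx(
            oracle_forward(model, seq), abs=1e-6
        )

    def test_forward_dominates_viterbi(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            m = int(rng.integers(1, 5))
            model = random_small_model(rng, m)
            seq = "".join(rng.choice(list(AMINO_ACIDS), size=int(rng.integers(1, 6))))
            assert forward_score(model, seq) >= viterbi_score(model, seq) - 1e-9

    def test_x_residue_contributes_zero_bits(self):
        model = one_state_model("A")
        assert viterbi_score(model, "X") == pytest.approx(0.0, abs=1e-9)


class TestScreen:
    def test_threshold_extremes(self, reference, anchor):
        family = synth.generate_family(reference, anchor, 3, 0.0, seed=0)
        model = build_from_msa(
            Msa(records=[(r.id, r.sequence) for r in family])
        )
        hits_all = screen(model, family, threshold=float("-inf"))
        assert all(h.passed for h in hits_all)
        top = max(h.bit_score for h in hits_all)
        hits_none = screen(model, family, threshold=top + 1)
        assert not any(h.passed for h in hits_none)

    def test_calibrated_threshold_passes_all_true(self, reference, anchor,
                                                  clean_screen_set):
        from mglscreen import pairwise

        family = synth.generate_family(reference, anchor, 6, 0.05, seed=13)
        model = build_from_msa(pairwise.reference_anchored_msa(reference, family))
        records, truth = clean_screen_set
        hits = screen(model, records, threshold=float("-inf"))
        truth_of = dict(zip(truth["id"], truth["truth_label"]))
        true_scores = [h.bit_score for h in hits if truth_of[h.id] == "true_mgl"]
        threshold = min(true_scores) - 1.0
        rehits = screen(model, records, threshold=threshold)
        assert all(
            h.passed for h in rehits if truth_of[h.id] == "true_mgl"
        )
        # background scores far below the family threshold
        assert all(
            h.bit_score < threshold
            for h in rehits
            if truth_of[h.id] == "background"
        )

    def test_scores_invariant_under_record_order(self, reference, anchor):
        family = synth.generate_family(reference, anchor, 4, 0.02, seed=3)
        model = build_from_msa(
            Msa(records=[(r.id, r.sequence) for r in family])
        )
        fwd = {h.id: h.bit_score for h in screen(model, family)}
        rev = {h.id: h.bit_score for h in screen(model, family[::-1])}
        assert fwd == rev


class TestHmmer3File:
    def _write_toy_profile(self, path):
        import pyhmmer

        abc = pyhmmer.easel.Alphabet.amino()
        h = pyhmmer.plan7.HMM(abc, 2, "toy")
        me = np.asarray(h.match_emissions)
        me[0, :] = 0.0
        me[0, 0] = 1.0
        row = np.zeros(20)
        row[AMINO_ACIDS.index("A")] = 1.0  # '*' fields for the rest
        me[1, :] = row
        row2 = np.full(20, 1 / 20)
        me[2, :] = row2
        np.asarray(h.insert_emissions)[:, :] = 1 / 20
        tp = np.asarray(h.transition_probabilities)
        tp[0] = [0.8, 0.1, 0.1, 0.5, 0.5, 1.0, 0.0]
        tp[1] = [0.7, 0.2, 0.1, 0.6, 0.4, 0.9, 0.1]
        tp[2] = [0.9, 0.1, 0.0, 1.0, 0.0, 1.0, 0.0]
        h.validate()
        with open(path, "wb") as fh:
            h.write(fh, binary=False)

    def test_read_fields(self, tmp_path):
        p = tmp_path / "toy.hmm"
        self._write_toy_profile(p)
        model = read_hmmer3_profile(p)
        assert model.length == 2
        # zero-probability fields ('*') survive as exact zeros
        assert model.match_emissions[0, AMINO_ACIDS.index("A")] == pytest.approx(
            1.0, abs=1e-5
        )
        assert model.match_emissions[0, 5] == 0.0
        assert model.transitions[1, MM] == pytest.approx(0.7, abs=1e-4)
        assert np.allclose(model.background.sum(), 1.0)

    def test_wrong_magic_rejected(self, tmp_path):
        p = tmp_path / "old.hmm"
        p.write_text("HMMER2.0 [2.3.2]\nNAME x\n//\n")
        with pytest.raises(FormatError):
            read_hmmer3_profile(p)

    def test_scores_usable_after_round_trip(self, tmp_path):
        p = tmp_path / "toy.hmm"
        self._write_toy_profile(p)
        model = read_hmmer3_profile(p)
        s = viterbi_score(model, "AC")
        assert np.isfinite(s)
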