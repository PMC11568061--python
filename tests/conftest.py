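import pytest

from mglscreen import synth


@pytest.fixture(scope="session")
def reference_and_anchor():
    """Synthetic 398-residue reference with YGC@114 and KD@240."""
    return synth.make_synthetic_reference()


@pytest.fixture(scope="session")
def reference(reference_and_anchor):
    return reference_and_anchor[0]


@pytest.fixture(scope="session")
def anchor(reference_and_anchor):
    return reference_and_anchor[1]


@pytest.fixture(scope="session")
def clean_screen_set(reference_and_anchor):
    """25-record set (5 per class), mutation rate 0, motif-free background.

    Seed 7 was verified to give a background class without accidental
    YGC occurrences; the fixture asserts that precondition.
    """
    ref, anc = reference_and_anchor
    config = synth.SynthConfig(
        n_true=5, n_no_ygc=5, n_no_kd=5, n_misplaced=5, n_background=5,
        mutation_rate=0.0, seed=7,
    )
    records, truth = synth.generate_screen_set(config, ref, anc)
    assert synth.background_is_motif_free(records, anc)
    return records, truth
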