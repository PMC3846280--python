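import pytest

from plescout import LocusSpec, forge_locus


@pytest.fixture(scope="session")
def pen2a():
    """A default (Pen2a-type) forged locus with its ground truth."""
    seq, truth = forge_locus(LocusSpec(seed=1), "pen2a")
    return seq, truth


@pytest.fixture(scope="session")
def pen2a_annotation(pen2a):
    from plescout.repeat_annotator import find_terminal_repeats, resolve_arrangement

    seq, truth = pen2a
    pairs = find_terminal_repeats(seq)
    return resolve_arrangement(pairs)
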