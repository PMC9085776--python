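import random

import pytest

from doubletap import LocusSequence, make_locus


@pytest.fixture
def rng():
    return random.Random(20240917)


@pytest.fixture(scope="session")
def locus_and_primary():
    """A 240-nt synthetic locus with a centred NGG protospacer."""
    return make_locus(seed=11, length=240)


@pytest.fixture(scope="session")
def hdr_allele(locus_and_primary):
    """HDR-edited amplicon: 4-nt insertion at the cut (a knock-in edit
    that also blocks the primary protospacer)."""
    from doubletap import IndelSpec, apply_indel

    locus, primary = locus_and_primary
    edit = IndelSpec(
        kind="insertion", length=4, anchor_cut=primary.cut_index,
        inserted="GATC",
    )
    return LocusSequence(
        id=f"{locus.id}_hdr", seq=apply_indel(locus, edit).seq
    )
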