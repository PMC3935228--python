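import pytest

from barcodegap import SequenceRecord, SequenceSet, reference


@pytest.fixture(scope="session")
def reference_set() -> SequenceSet:
    """The three published full-length reference barcodes."""
    return reference.reference_sequence_set()


@pytest.fixture(scope="session")
def reference_labels(reference_set) -> dict:
    return {r.id: r.species for r in reference_set}


@pytest.fixture()
def toy_alignment() -> SequenceSet:
    """Tiny three-group alignment with known fixed differences."""
    return SequenceSet(
        [
            SequenceRecord("a1", "AAACCCGGGT", species="A"),
            SequenceRecord("a2", "AAACCCGGGT", species="A"),
            SequenceRecord("b1", "AATCCCGGCT", species="B"),
            SequenceRecord("b2", "AATCCCGGCT", species="B"),
            SequenceRecord("c1", "AATCCAGGCT", species="C"),
            SequenceRecord("c2", "AATCCAGGCT", species="C"),
        ]
    )
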