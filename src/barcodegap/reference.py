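"""Reference COI barcodes, mini-barcode primers and diagnostic positions.

Three published full-length (658 bp) COI barcodes of the USA *Hermeuptychia*
species anchor the whole pipeline: the *H. sosybius* neotype (GenBank
KJ025561), the *H. intricata* holotype (KJ025595) and the most common
*H. hermybius* haplotype (voucher NVG-1603, KJ025569).  The four styr-ID
primers amplify two very short "ID tag" regions designed for degraded museum
DNA, and the 11 diagnostic positions separate *H. hermybius* from
*H. sosybius* (1-based on the 658-bp barcode).
"""

from __future__ import annotations

from .diagnostics import Primer
from .seqio import SequenceRecord, SequenceSet

SOSYBIUS_NEOTYPE = SequenceRecord(
    id="KJ025561",
    species="Hermeuptychia sosybius",
    residues=(
        "AACTTTATATTTTATTTTTGGTATTTGAGCAGGAATAATTGGAACATCATTAAGTTTAATTATCCGAATAG"
        "AATTAGGTAACCCAGGATTTTTAATTGGAGATGACCAAATTTATAATACTATTGTTACAGCTCATGCTTTT"
        "ATTATAATTTTTTTTATAGTAATACCTATTATAATTGGAGGATTTGGTAATTGACTTATTCCTTTAATATT"
        "AGGAGCTCCTGATATAGCTTTTCCGCGTATAAATAATATAAGATTTTGATTATTACCTCCATCTTTAATTT"
        "TATTAATTTCTAGCAGTATTGTAGAAAATGGAAGTGGAACAGGATGAACTGTTTACCCCCCTCTTTCATCT"
        "AATATTGCTCATAGAGGTTCTTCAGTAGATTTAGCAATTTTTTCTCTTCATTTAGCTGGAATTTCATCAAT"
        "TTTAGGAGCTATTAATTTTATTACAACAATTATTAATATACGAATTAATAATATATCTTATGATCAAATAC"
        "CTTTATTTATTTGAGCTGTAGGAATTACTGCTCTTCTTTTACTTCTCTCATTACCTGTTTTAGCAGGAGCT"
        "ATTACCATACTTCTTACTGATCGAAATTTAAATACATCATTTTTTGATCCTGCAGGAGGAGGAGATCCTAT"
        "TTTATATCAACATTTATTT"
    ),
)

INTRICATA_HOLOTYPE = SequenceRecord(
    id="KJ025595",
    species="Hermeuptychia intricata",
    residues=(
        "AACTTTATATTTTATTTTTGGTATTTGAGCAGGAATAATTGGTACATCATTAAGTTTAATTATCCGAATAG"
        "AATTAGGTAATCCAGGATTTTTAATTGGAGATGACCAAATTTATAATACTATTGTTACAGCTCATGCTTTT"
        "ATTATAATTTTTTTTATAGTAATACCCATTATAATTGGAGGATTTGGTAATTGACTTGTCCCTTTAATATT"
        "AGGAGCTCCTGATATAGCTTTCCCACGTATAAATAATATAAGATTTTGATTATTACCCCCATCTTTAATTT"
        "TATTAATTTCTAGTAGTATTGTAGAAAATGGAAGTGGGACAGGATGAACAGTTTACCCCCCCCTCTCATCT"
        "AATATTGCTCATAGAGGTTCTTCAGTAGATTTAACAATTTTTTCACTTCATTTAGCTGGAATTTCTTCAAT"
        "CTTAGGAGCTATTAATTTTATTACAACAATTATTAACATACGAATCAATAATATATCTTATGATCAAATAC"
        "CTTTATTTATTTGAGCTGTAGGAATTACAGCTCTTCTTTTACTTCTTTCATTACCTGTTTTAGCAGGAGCT"
        "ATTACTATACTTCTTACTGATCGAAATTTAAATACATCATTTTTTGATCCTGCAGGAGGAGGAGATCCTAT"
        "TTTATATCAACATTTATTT"
    ),
)

HERMYBIUS_REFERENCE = SequenceRecord(
    id="KJ025569",
    species="Hermeuptychia hermybius",
    residues=(
        "AACTTTATATTTTATTTTTGGTATTTGAGCAGGAATAATTGGAACATCATTAAGTTTAATTATTCGAATAG"
        "AGTTAGGTAATCCAGGATTTTTAATTGGAGATGACCAAATTTATAACACTATTGTTACAGCCCATGCTTTT"
        "ATTATAATTTTTTTTATAGTAATACCTATTATAATTGGAGGATTTGGTAATTGACTTATTCCTTTAATATT"
        "AGGAGCTCCTGATATAGCTTTCCCACGTATAAATAATATAAGATTTTGATTATTACCCCCATCTTTAATTT"
        "TATTAATTTCTAGTAGTATTGTAGAAAATGGAAGTGGAACAGGATGAACTGTTTACCCCCCTCTTTCATCT"
        "AATATTGCCCATAGAGGTTCTTCAGTAGATTTAGCAATTTTTTCTCTTCATTTAGCTGGAATTTCATCAAT"
        "TTTAGGAGCCATTAATTTTATTACAACAATTATTAATATACGAATTAATAATATATCTTATGATCAAATAC"
        "CTTTATTTATTTGAGCTGTAGGAATTACAGCTCTTCTTTTACTTCTCTCATTACCTGTTTTAGCAGGAGCT"
        "ATTACCATACTTCTTACTGATCGAAATTTAAATACATCATTTTTTGACCCTGCAGGAGGAGGAGATCCTAT"
        "TTTATATCAACATTTATTT"
    ),
)

#: The two ID-tag primer pairs (forward primer, reverse primer).
STYR_ID1F = Primer(name="styr-ID1F", residues="TTGAGCAGGAATAATTGGWACAT", orientation="forward")
STYR_ID1R = Primer(name="styr-ID1R", residues="AAAAGCATGRGCTGTAACAA", orientation="reverse")
STYR_ID2F = Primer(name="styr-ID2F", residues="TTGGAGGATTTGGTAATTGACTT", orientation="forward")
STYR_ID2R = Primer(name="styr-ID2R", residues="AAAGATGGRGGTAATAATCAAAAT", orientation="reverse")

ID_TAG_PRIMERS: dict[int, tuple[Primer, Primer]] = {
    1: (STYR_ID1F, STYR_ID1R),
    2: (STYR_ID2F, STYR_ID2R),
}

#: Published diagnostic positions distinguishing H. hermybius from
#: H. sosybius: (position, hermybius state, sosybius state), 1-based.
HERMYBIUS_VS_SOSYBIUS_POSITIONS: list[tuple[int, str, str]] = [
    (64, "T", "C"),
    (73, "G", "A"),
    (82, "T", "C"),
    (118, "C", "T"),
    (133, "C", "T"),
    (235, "C", "T"),
    (238, "A", "G"),
    (364, "C", "T"),
    (436, "C", "T"),
    (526, "A", "T"),
    (616, "C", "T"),
]

#: GenBank accession range of the study's newly sequenced specimens.
ACCESSION_FIRST = "KJ025523"
ACCESSION_LAST = "KJ025607"


def reference_sequence_set() -> SequenceSet:
    """The three reference barcodes as one aligned set."""
    return SequenceSet(
        [SOSYBIUS_NEOTYPE, HERMYBIUS_REFERENCE, INTRICATA_HOLOTYPE]
    )
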