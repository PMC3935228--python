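"""Mini-barcode ("ID tag") workflow for degraded museum DNA.

Runs virtual PCR with the two styr-ID primer pairs on the reference
barcodes, shows the diagnostic sites inside the tag-2 insert, and calls the
species of a short fragment extracted from each barcode — the strategy used
to identify specimens over a century old.
"""

from barcodegap import (
    SequenceRecord,
    SequenceSet,
    call_species,
    find_diagnostic_sites,
    virtual_pcr,
)
from barcodegap.reference import (
    ID_TAG_PRIMERS,
    SOSYBIUS_NEOTYPE,
    reference_sequence_set,
)

seqs = reference_sequence_set()
labels = {r.id: r.species for r in seqs}
sites = find_diagnostic_sites(seqs, labels)
print(f"{len(sites)} three-species diagnostic sites on the 658-bp barcode")

for tag, (fwd, rev) in ID_TAG_PRIMERS.items():
    amp = virtual_pcr(SOSYBIUS_NEOTYPE, fwd, rev)
    print(
        f"ID tag {tag}: insert {amp.insert_len} bp, "
        f"full product {amp.product_len} bp "
        f"(primers bind at {amp.forward_interval} and {amp.reverse_interval})"
    )

amp2 = virtual_pcr(SOSYBIUS_NEOTYPE, *ID_TAG_PRIMERS[2])
s, e = amp2.insert_interval
print(f"\nCalling species from the tag-2 insert ({s}-{e}):")
for rec in seqs:
    frag = SequenceRecord("frag", rec.residues[s - 1 : e])
    call = call_species(frag, sites, offset=s)
    print(f"  fragment of {rec.id}: called {call.verdict}")
print(
    "\nA ~56 bp insert suffices: every species differs from the others by "
    "at least 2 nucleotides inside this window."
)
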