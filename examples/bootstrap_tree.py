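"""Bootstrap supports on a BioNJ tree from simulated barcodes.

Builds the tree for a small simulated sample (3 species x 4 haplotypes) and
reports bootstrap support for the species-splitting edges: columns are
resampled with replacement, the tree rebuilt, and each edge's support is
the percentage of replicates containing the same bipartition.
"""

import tempfile
from pathlib import Path

from barcodegap import SimulationConfig, bootstrap, simulate_species_set, write_newick

seqs, truth = simulate_species_set(SimulationConfig(n_per_species=4, seed=7))
res = bootstrap(seqs, metric="k2p", n_reps=100, seed=7)

print(f"replicates: {res.n_replicates}, skipped for saturation: {res.n_skipped}")


def show(node, depth=0):
    if node.is_leaf:
        return
    if node.support is not None:
        members = sorted(lf.label for lf in node.leaves())
        print(f"  support {node.support:5.1f}%  clade {{{', '.join(members)}}}")
    for ch in node.children:
        show(ch, depth + 1)


show(res.tree.root)
out = write_newick(res.tree, Path(tempfile.mkdtemp()) / "bootstrap_tree.nwk")
print(f"\nnewick with supports written to {out}")
print(
    "Edges separating whole species get near-100% support; edges among "
    "nearly identical within-species haplotypes are weakly supported, as "
    "expected when haplotypes differ by only 1-3 substitutions."
)
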