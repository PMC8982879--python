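"""Build the graph representation of one protein chain.

Generates a small synthetic helix bundle, writes it as a PDB file,
reloads it, and shows the complete-graph adjacency and the invariant
node features every downstream stage consumes.
"""

import tempfile
from pathlib import Path

import numpy as np

import foldgraph as fg

with tempfile.TemporaryDirectory() as tmp:
    structure = fg.generate_archetype("helix_bundle", length=50, seed=3)
    path = Path(tmp) / "bundle.pdb"
    fg.write_structure(structure, path)
    (loaded,) = fg.load_structures(path)

graph = fg.featurize(loaded, M=5)
print(f"structure: {loaded.id}, {loaded.n_residues} residues")
print(f"adjacency: {graph.adjacency.shape}, "
      f"range ({graph.adjacency.min():.3f}, {graph.adjacency.max():.3f}]")
print(f"node features: {graph.node_features.shape} "
      f"(31 reference-point distances + 1 bend-angle cosine per residue)")

# the representation ignores where the molecule sits in space
rng = np.random.default_rng(0)
R = fg.synthetic.random_rotation(rng)
moved = fg.ProteinStructure(
    id="moved", ca_coords=loaded.ca_coords @ R.T + rng.uniform(-30, 30, 3)
)
drift = np.abs(fg.featurize(moved).node_features - graph.node_features).max()
print(f"feature drift after a random rigid motion: {drift:.2e} "
      f"(rotation/translation invariant)")
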