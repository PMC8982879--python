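"""Superpose two structures from residue-level descriptors alone.

No sequence, no iterative structural alignment: residue embeddings from
the encoder give a cosine-similarity matrix, Needleman-Wunsch turns it
into a residue correspondence, and the Kabsch algorithm superposes the
C-alpha traces.  A same-family pair should land at a much lower RMSD
than two unrelated folds.
"""

import tempfile
from pathlib import Path

import foldgraph as fg

encoder = fg.GraphEncoder(fg.EncoderConfig.small(), seed=0)

parent = fg.generate_archetype("helix_bundle", length=52, seed=5)
sibling = fg.perturb_member(parent, scale=0.5, seed=6)   # same family
stranger = fg.generate_archetype("sheet", length=52, seed=7)  # other fold

with tempfile.TemporaryDirectory() as tmp:
    out = Path(tmp) / "superposed.pdb"
    fam = fg.superpose(parent, sibling, encoder, out_path=out)
    print(f"superposed pair written with {out.read_text().count('MODEL')} models")
cross = fg.superpose(parent, stranger, encoder)

print(f"same family : {len(fam.pairs)} aligned residues, "
      f"RMSD {fam.rmsd:.2f} A")
print(f"cross fold  : {len(cross.pairs)} aligned residues, "
      f"RMSD {cross.rmsd:.2f} A")
print("lower same-family RMSD means the residue embeddings recover the "
      "correspondence implicitly; no alignment was used in training")
print(f"oracle TM same family {fg.tm_oracle(parent, sibling):.3f} "
      f"vs cross fold {fg.tm_oracle(parent, stranger):.3f}")
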