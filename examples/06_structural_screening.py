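"""Screen candidate substitutions against a structure.

Builds a small synthetic structure (single-atom residues on a line, 5 Å
apart) so every distance is known by construction, then applies the two
geometric filters: the >6 Å active-site exclusion and the side-chain
hydrogen-bond / salt-bridge exclusion.
"""

import tempfile
from pathlib import Path

from phyloconsensus import apply_structural_filters, load_structure
from phyloconsensus.consensus import CandidateSite

pdb = Path(tempfile.mkdtemp()) / "synthetic_query.pdb"
with open(pdb, "w") as fh:
    for i in range(8):  # eight glycines along x, 5 Å apart
        fh.write(
            f"ATOM  {i + 1:>5}  CA  GLY A{i + 1:>4}    "
            f"{5.0 * i:8.3f}{0.0:8.3f}{0.0:8.3f}  1.00  0.00           C\n"
        )
    fh.write("END\n")

model = load_structure(pdb, query_sequence="G" * 8)
candidates = [
    CandidateSite(2, "G", "A", 72.0),   # 5 Å from the active site
    CandidateSite(4, "G", "S", 55.0),   # 15 Å away
    CandidateSite(7, "G", "V", 48.0),   # 30 Å away
]
screened = apply_structural_filters(candidates, model, active_site=[1])
print("active site: residue 1; exclusion radius 6.0 Å")
for site in screened:
    print(f"  {site.label:>5}  {site.distance_to_active_site:5.1f} Å  "
          f"{site.filter_status}")
# G2A sits 5 Å from the declared active site and is rejected; the distant
# sites pass (glycine has no side chain, so no bonding rejections here).
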