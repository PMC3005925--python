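"""Derive the Boolean behaviour of every construct in two host strains.

Each plasmid is assembled from scratch, its regulatory model read off the
annotations, and the truth table evaluated over all inducer combinations.
In the LacI-expressing strain the two-operator construct is a genetic AND
gate: transcription only with both IPTG (releases the LacI repressor) and
AHL (enables the LuxR activator). In a strain without LacI the same DNA
behaves like a buffer on AHL — regulation needs the regulator.
"""

from opergate import build_plasmid, extract_model, truth_table
from opergate.fixtures import PLASMID_NAMES, load_strains

strains = load_strains()
for strain in ("DH5alphaLacI", "DH5alpha"):
    print(f"strain {strain} (expresses: {sorted(strains[strain]) or 'nothing'})")
    for name in PLASMID_NAMES:
        plasmid = build_plasmid(name, seed=0)
        table = truth_table(extract_model(plasmid, strains[strain]))
        doc = table.as_dict()
        rows = ", ".join(f"{k}={v}" for k, v in doc["rows"].items())
        print(f"  {name:<22} gate={doc['gate']:<12} {rows}")
    print()
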