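"""Design a downstream operator part and check it against the standard.

The part standard wraps any operator sequence into an insertable duplex:
BamHI-compatible GATC overhang, the operator, a fresh BglII site, a spacer,
and an MluI-compatible CGCG overhang. The printed oligo pair is what you
would order from a synthesis house; annealing them gives the part itself.
"""

from opergate import RegulatorSpec, design_downstream_part, validate_downstream_part
from opergate.errors import DesignError

laci = RegulatorSpec("LacI", "repressor", "IPTG")
top, bottom, part = design_downstream_part(
    operator_seq="GGAATTGTGAGCGGATAACAATTCC",  # symmetric lac operator
    spacer="ATCGTAA",
    regulator=laci,
    name="lacO",
)
print(f"order these oligos:\n  top:    5'-{top}-3'\n  bottom: 5'-{bottom}-3'")
print(f"annealed part: {len(part.fragment.core_top)} bp double-stranded core, "
      f"ends 5'-{part.fragment.left_end.overhang} / 5'-{part.fragment.right_end.overhang}")

report = validate_downstream_part(part)
for check, ok, _detail in report.findings:
    print(f"  {'PASS' if ok else 'FAIL'} {check}")
print(f"conforms to the downstream part standard: {report.conforms}")

# a payload carrying a forbidden site is refused with the site named
try:
    design_downstream_part("GGAATTACGCGTAATTCC", "ATCGTAA", laci)
except DesignError as exc:
    print(f"forbidden payload refused: {exc}")
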