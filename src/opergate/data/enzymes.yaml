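# Built-in type-II restriction enzyme table, version 1.
#
# Each entry: palindromic recognition site and the top-strand cut offset
# (bases from the recognition start to the top-strand cut). All seven
# enzymes leave 4-nt 5' overhangs. Geometries follow the standard REBASE
# definitions; the table is data, not code, so a project can override it
# with its own file of the same shape.
version: 1
enzymes:
  - {name: EcoRI, recognition: GAATTC, cut_offset_top: 1}   # G^AATTC
  - {name: XbaI,  recognition: TCTAGA, cut_offset_top: 1}   # T^CTAGA
  - {name: SalI,  recognition: GTCGAC, cut_offset_top: 1}   # G^TCGAC
  - {name: BamHI, recognition: GGATCC, cut_offset_top: 1}   # G^GATCC
  - {name: BglII, recognition: AGATCT, cut_offset_top: 1}   # A^GATCT
  - {name: MluI,  recognition: ACGCGT, cut_offset_top: 1}   # A^CGCGT
  - {name: SpeI,  recognition: ACTAGT, cut_offset_top: 1}   # A^CTAGT
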