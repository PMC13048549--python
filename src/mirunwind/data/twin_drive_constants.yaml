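# Twin-drive strand-selection constants: ln(5p/3p) = k*ddG(5p-3p) + N[nt5p] - N[nt3p]
#
# k weighs the duplex-end stability difference (units: 1/(kcal/mol)).  It is
# negative because the end that is cheaper to unwind (smaller unwinding
# energy) is the one Argonaute prefers to load, promoting the strand whose
# 5' terminus sits at that end.
#
# N maps the 5'-terminal nucleotide of each strand to its identity-drive
# value, respecting the MID-domain preference ordering U > A > G > C.
#
# These are mirunwind package defaults chosen to reproduce the published
# qualitative ordering and sign conventions of the twin-drive model; they
# are NOT fitted values.  Substitute the constants of the twin-drive source
# publication (or your own fit) via --params / load_params for quantitative
# work.
k: -0.5
N:
  U: 2.0
  A: 1.5
  G: 0.5
  C: 0.0
provenance: mirunwind package defaults (twin-drive functional form; unfitted)
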