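# Coarse-grained (MARTINI-style) lipid segment scheme.
# First matching "residue <resname> <particle-pattern> <segment>" rule wins.
# Segments: head_terminal phosphate glycerol tail

alias DMP DMPC
alias DPP DPPC
alias DSP DSPE

# phosphatidylcholines: choline bead NC3, phosphate PO4, glycerol GL1/GL2,
# acyl tail beads C?A / C?B (and unsaturated D?A / D?B)
residue DMPC NC3 head_terminal
residue DMPC PO4 phosphate
residue DMPC GL* glycerol
residue DMPC C?A tail
residue DMPC C?B tail

residue DPPC NC3 head_terminal
residue DPPC PO4 phosphate
residue DPPC GL* glycerol
residue DPPC C?A tail
residue DPPC C?B tail

# phosphatidylethanolamine: terminal amine bead NH3 plays the choline role
residue DSPE NH3 head_terminal
residue DSPE PO4 phosphate
residue DSPE GL* glycerol
residue DSPE C?A tail
residue DSPE C?B tail

role W solvent
role PW solvent
role ION other
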