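# Atomistic lipid segment scheme (CHARMM-style heavy-atom names).
# First matching rule wins: keep specific rules (C21 carbonyl) before broad
# ones (C2* tail).  Hydrogen rules are best-effort region patterns with a
# tail catch-all; contact analysis is heavy-atom based, so hydrogen segment
# labels never enter the statistics.

alias DMP DMPC
alias DPP DPPC
alias DSP DSPE
alias PX4 DMPC   # PDB chemical-component code for DMPC
alias 3PE DSPE   # PDB chemical-component code used for modeled PE lipids

residue DMPC N head_terminal
residue DMPC C1[12345] head_terminal
residue DMPC P phosphate
residue DMPC O1[1234] phosphate
residue DMPC C1 glycerol
residue DMPC C2 glycerol
residue DMPC C3 glycerol
residue DMPC O2[12] glycerol
residue DMPC O3[12] glycerol
residue DMPC C21 glycerol
residue DMPC C31 glycerol
residue DMPC C2* tail
residue DMPC C3* tail
residue DMPC H1[12345]* head_terminal
residue DMPC H[ABXYS] glycerol
residue DMPC H* tail

residue DPPC N head_terminal
residue DPPC C1[12345] head_terminal
residue DPPC P phosphate
residue DPPC O1[1234] phosphate
residue DPPC C1 glycerol
residue DPPC C2 glycerol
residue DPPC C3 glycerol
residue DPPC O2[12] glycerol
residue DPPC O3[12] glycerol
residue DPPC C21 glycerol
residue DPPC C31 glycerol
residue DPPC C2* tail
residue DPPC C3* tail
residue DPPC H1[12345]* head_terminal
residue DPPC H[ABXYS] glycerol
residue DPPC H* tail

# PE head group: the terminal amine nitrogen takes the head_terminal role
residue DSPE N head_terminal
residue DSPE C1[12] head_terminal
residue DSPE P phosphate
residue DSPE O1[1234] phosphate
residue DSPE C1 glycerol
residue DSPE C2 glycerol
residue DSPE C3 glycerol
residue DSPE O2[12] glycerol
residue DSPE O3[12] glycerol
residue DSPE C21 glycerol
residue DSPE C31 glycerol
residue DSPE C2* tail
residue DSPE C3* tail
residue DSPE HN* head_terminal
residue DSPE H1[12]* head_terminal
residue DSPE H[ABXYS] glycerol
residue DSPE H* tail

role HOH solvent
role SOL solvent
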