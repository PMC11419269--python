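# Screened segment coordinates, 1-based inclusive on the full precursor.
# TREM2 motifs: the three CDR loops of the hydrophobic site and the four
# strands of the basic site; target = immunoglobulin domain.
trem2.target=18-130
trem2.CDR1=39-46
trem2.CDR2=69-75
trem2.CDR3=88-91
trem2.Basic strand 1=47-50
trem2.Basic strand 2=62-68
trem2.Basic strand 3=76-78
trem2.Basic strand 4=112-114
# IL-34 motifs: the six helices of the cytokine fold; target = mature
# protein (signal peptide 1-20 excluded).
il34.target=21-242
il34.Helix 1=31-54
il34.Helix 2=71-85
il34.Helix 3=90-100
il34.Helix 4=119-129
il34.Helix 5=142-151
il34.Helix 6=156-179
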