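# Shipped post-translational modification dictionary: name -> elemental
# composition added to the peptide.  Extend by passing an additional file
# with the same layout.  "acetyl:13C2" denotes the acetyl group whose two
# carbons come from a 13C2 tracer pool; its composition delta is identical
# to acetyl -- the label is declared separately through the label
# specification, not here.
acetyl: C2H2O
"acetyl:13C2": C2H2O
carbamidomethyl: C2H3NO
phospho: HPO3
methyl: CH2
dimethyl: C2H4
trimethyl: C3H6
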