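>A1_LCD reconstructed low-complexity domain of human hnRNPA1 (UniProt P09651, isoform A1-A residues 186-320) with the PY motif of the M9 NLS substituted by GS; 135 residues
MASASSSQRGRSGSGNFGGGRGGGFGGNDNFGRGGNFSGRGGFGGSRGGGG
YGGSGDGYNGFGNDGSNFGGGGSYNDFGNYNNQSSNFGPMKGGNFGGRSS
GGSGGGGQYFAKPRNQGGYGGSSSSSSYGSGRRF
>A1_LCD_12D synthetic stand-in: A1_LCD with twelve Gly/Ser spacers substituted to Asp at near-uniformly spaced positions (6,18,27,39,51,63,74,85,97,107,119,130; 1-based); the exact substitution positions of the published variant are not reproduced here
MASASDSQRGRSGSGNFDGGRGGGFGDNDNFGRGGNFSDRGGFGGSRGGGD
YGGSGDGYNGFDNDGSNFGGGGDYNDFGNYNNQDSNFGPMKGGNFDGRSS
GGSGGDGQYFAKPRNQGDYGGSSSSSSYDSGRRF
>FUS_LCD reconstructed low-complexity domain of human FUS (UniProt P35637 residues 1-214); 214 residues
MASNDYTQQATQSYGAYPTQPGQGYSQQSSQPYGQQSYSGYSQSTDTSGY
GQSSYSSYGQSQNTGYGTQSTPQGYGSTGGYGSSQSSQSSYGQQSSYPGY
GQQPAPSSTSGSYGSSSQSSSYGQPQSGSYSQQPSYGGQQQSYGQQQSYN
PPQGYGQQNQYNSSSGGGGGGGGGGNYGQDQSSMSSGGGSGGGYGNQDQS
SGGSGGGYGQQDRG
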