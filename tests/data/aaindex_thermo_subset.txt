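H FUKS010101
D Surface composition of amino acids in intracellular proteins of thermophiles
D (percent) (Fukuchi-Nishikawa, 2001)
R PMID:11551177
A Fukuchi, S. and Nishikawa, K.
T Protein surface amino acid compositions distinctively differ between
T thermophilic and mesophilic bacteria
J J. Mol. Biol. 309, 835-843 (2001)
C FUKS010102    0.967
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    4.47    8.48    3.89    7.05    0.29    2.87   16.56    8.29    1.74    3.30
    5.06   12.98    1.71    2.32    5.41    4.27    3.83    0.67    4.05    2.75
//
H FUKS010102
D Surface composition of amino acids in intracellular proteins of mesophiles
D (percent) (Fukuchi-Nishikawa, 2001)
R PMID:11551177
A Fukuchi, S. and Nishikawa, K.
T Protein surface amino acid compositions distinctively differ between
T thermophilic and mesophilic bacteria
J J. Mol. Biol. 309, 835-843 (2001)
C FUKS010101    0.967
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    6.77    6.87    5.50    8.57    0.31    5.24   12.93    7.95    2.80    2.72
    4.43   10.20    1.87    1.92    4.79    5.41    5.36    0.54    3.57    2.26
//
H ZIMJ680101
D Hydrophobicity (Zimmerman et al., 1968)
R PMID:5700434
A Zimmerman, J.M., Eliezer, N. and Simha, R.
T The characterization of amino acid sequences in proteins by statistical
T methods
J J. Theor. Biol. 21, 170-201 (1968)
C JOND750101    0.941
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.83    0.83    0.09    0.64    1.48    0.00    0.65    0.10    1.10    3.07
    2.52    1.60    1.40    2.75    2.70    0.14    0.54    0.31    1.79    2.97
//
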