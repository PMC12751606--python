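# Amino-acid propensity table: one physicochemical scale per row, one
# column per standard residue (column order given by the header row).
# BASIC/ACID/POLAR/NONPOLAR are class-membership indicators; MASS is the
# average residue mass and MASSMR the free amino-acid molecular weight;
# the remaining four rows are hydropathy-type indices from the AAindex
# collection (Parker HPLC hydrophilicity, Jones hydrophobicity, Eisenberg
# consensus hydrophobicity, Juretic modified Kyte-Doolittle).
# Exact numeric values are configuration, not ground truth.
AA          A       C       D       E       F       G       H       I       K       L       M       N       P       Q       R       S       T       V       W       Y
BASIC       0       0       0       0       0       0       1       0       1       0       0       0       0       0       1       0       0       0       0       0
ACID        0       0       1       1       0       0       0       0       0       0       0       0       0       0       0       0       0       0       0       0
POLAR       0       1       1       1       0       0       1       0       1       0       0       1       0       1       1       1       1       0       0       1
NONPOLAR    1       0       0       0       1       1       0       1       0       1       1       0       1       0       0       0       0       1       1       0
MASS        71.08   103.14  115.09  129.12  147.18  57.05   137.14  113.16  128.17  113.16  131.19  114.10  97.12   128.13  156.19  87.08   101.10  99.13   186.21  163.18
MASSMR      89.09   121.16  133.10  147.13  165.19  75.07   155.16  131.17  146.19  131.17  149.21  132.12  115.13  146.15  174.20  105.09  119.12  117.15  204.23  181.19
PARJ860101  2.1     1.4     10.0    7.8     -9.2    5.7     2.1     -8.0    5.7     -9.2    -4.2    7.0     2.1     6.0     4.2     6.5     5.2     -3.7    -10.0   -1.9
JOND750101  0.87    1.52    0.66    0.67    2.87    0.10    0.87    3.15    1.64    2.17    1.67    0.09    2.77    0.00    0.85    0.07    0.07    1.87    3.77    2.67
EISD840101  0.25    0.04    -0.72   -0.62   0.61    0.16    -0.40   0.73    -1.10   0.53    0.26    -0.64   -0.07   -0.69   -1.76   -0.26   -0.18   0.54    0.37    0.02
JURD980101  1.10    2.50    -3.60   -3.20   2.80    -0.64   -3.20   4.50    -4.11   3.80    1.90    -3.50   -1.90   -3.68   -5.10   -0.50   -0.70   4.20    -0.46   -1.30
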