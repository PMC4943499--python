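"""Vendored per-amino-acid property tables.

HQI8: eight representative AAindex entries, one per property cluster
(electric properties BLAM930101, hydrophobicity BIOV880101, alpha/turn
propensity MAXF760101, physicochemical TSAJ990101, residue propensity
NAKH920108, composition CEDJ970104, beta propensity LIFS790101, intrinsic
propensity MIYS990104).

AA_FACTORS: five summary scores per amino acid (polarity, secondary
structure, molecular volume, codon diversity, electrostatic charge).

Pipeline code treats these as opaque lookup tables; nothing downstream
depends on the specific numeric values.
"""

HQI8_ACCESSIONS = (
    "BLAM930101", "BIOV880101", "MAXF760101", "TSAJ990101",
    "NAKH920108", "CEDJ970104", "LIFS790101", "MIYS990104",
)

HQI8 = {
    #      BLAM    BIOV   MAXF   TSAJ    NAKH   CEDJ   LIFS   MIYS
    "A": [0.96,   16.0,  1.43,  89.3,   9.25,  7.9,  0.92, -0.04],
    "R": [0.77,  -70.0,  1.18, 190.3,   3.96,  4.9,  0.93,  0.07],
    "N": [0.39,  -74.0,  0.64, 122.4,   3.71,  4.0,  0.60,  0.13],
    "D": [0.42,  -78.0,  0.92, 114.4,   3.89,  5.5,  0.48,  0.19],
    "C": [0.42,  168.0,  0.94, 102.5,   1.07,  1.9,  1.16, -0.38],
    "Q": [0.80,  -73.0,  1.22, 146.9,   3.17,  4.4,  0.95,  0.14],
    "E": [0.53, -106.0,  1.67, 138.8,   4.80,  7.1,  0.61,  0.23],
    "G": [0.00,  -13.0,  0.46,  63.8,   8.51,  7.1,  0.61,  0.09],
    "H": [0.57,   50.0,  0.98, 157.5,   1.88,  2.1,  0.93, -0.04],
    "I": [0.84,  151.0,  1.04, 163.0,   6.47,  5.2,  1.81, -0.34],
    "L": [0.92,  145.0,  1.36, 163.1,  10.94,  8.6,  1.30, -0.37],
    "K": [0.73, -141.0,  1.27, 165.1,   5.19,  6.7,  0.70,  0.33],
    "M": [0.86,  124.0,  1.53, 165.8,   2.67,  2.4,  1.19, -0.30],
    "F": [0.59,  189.0,  1.19, 190.8,   6.36,  3.9,  1.25, -0.38],
    "P": [-2.50, -20.0,  0.49, 121.6,   4.36,  5.3,  0.40,  0.19],
    "S": [0.53,  -70.0,  0.70,  94.2,   5.27,  6.6,  0.82,  0.12],
    "T": [0.54,  -38.0,  0.78, 119.6,   5.53,  5.3,  1.12,  0.03],
    "W": [0.58,  145.0,  1.01, 226.4,   1.51,  1.2,  1.54, -0.33],
    "Y": [0.72,   53.0,  0.69, 194.6,   3.13,  3.1,  1.53, -0.29],
    "V": [0.63,  123.0,  0.98, 138.2,   7.33,  6.8,  1.81, -0.29],
}

AA_FACTOR_NAMES = (
    "polarity", "secondary_structure", "molecular_volume",
    "codon_diversity", "electrostatic_charge",
)

AA_FACTORS = {
    "A": [-0.591, -1.302, -0.733,  1.570, -0.146],
    "C": [-1.343,  0.465, -0.862, -1.020, -0.255],
    "D": [ 1.050,  0.302, -3.656, -0.259, -3.242],
    "E": [ 1.357, -1.453,  1.477,  0.113, -0.837],
    "F": [-1.006, -0.590,  1.891, -0.397,  0.412],
    "G": [-0.384,  1.652,  1.330,  1.045,  2.064],
    "H": [ 0.336, -0.417, -1.673, -1.474, -0.078],
    "I": [-1.239, -0.547,  2.131,  0.393,  0.816],
    "K": [ 1.831, -0.561,  0.533, -0.277,  1.648],
    "L": [-1.019, -0.987, -1.505,  1.266, -0.912],
    "M": [-0.663, -1.524,  2.219, -1.005,  1.212],
    "N": [ 0.945,  0.828,  1.299, -0.169,  0.933],
    "P": [ 0.189,  2.081, -1.628,  0.421, -1.392],
    "Q": [ 0.931, -0.179, -3.005, -0.503, -1.853],
    "R": [ 1.538, -0.055,  1.502,  0.440,  2.897],
    "S": [-0.228,  1.399, -4.760,  0.670, -2.647],
    "T": [-0.032,  0.326,  2.213,  0.908,  1.313],
    "V": [-1.337, -0.279, -0.544,  1.242, -1.262],
    "W": [-0.595,  0.009,  0.672, -2.128, -0.184],
    "Y": [ 0.260,  0.830,  3.097, -0.838,  1.512],
}
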