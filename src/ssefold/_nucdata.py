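"""Frozen standard-nucleotide coordinates (see ssefold.nucgeom)."""

# Heavy-atom coordinates of each base type in the standard pair frame, Å.
# Derived once from chemical-component ideal residue geometry fitted into
# the pair frame, with the shared sugar-phosphate backbone least-squares
# refined for A-form helical continuity (O3'-P = 1.60 Å on both strands)
# at twist 32.7 deg, rise 2.81 Å, inclination 18.8 deg (folded into the
# coordinates) and axis displacement -3.136 Å.

NUCLEOTIDE_COORDS = {
    'A': {
        'P': (1.3777, 8.0736, 3.7836),
        'OP1': (0.9842, 9.4992, 3.7800),
        'OP2': (2.8157, 7.9150, 4.4884),
        "O5'": (0.2844, 7.2171, 4.5970),
        "C5'": (-0.1971, 6.2054, 3.7126),
        "C4'": (-1.7074, 6.3607, 3.5348),
        "O4'": (-2.0602, 6.4245, 2.1416),
        "C3'": (-2.4598, 5.1638, 4.1492),
        "O3'": (-3.3707, 5.6067, 5.1579),
        "C2'": (-3.2324, 4.5469, 2.9601),
        "O2'": (-4.5877, 4.9999, 2.9551),
        "C1'": (-2.4652, 5.1020, 1.7384),
        'N9': (-1.2994, 4.2655, 1.4473),
        'C8': (0.0073, 4.6333, 1.5685),
        'N7': (0.7811, 3.6446, 1.2269),
        'C5': (0.0232, 2.5804, 0.8715),
        'C6': (0.2969, 1.2790, 0.4173),
        'N6': (1.6014, 0.8435, 0.2626),
        'N1': (-0.7246, 0.4744, 0.1461),
        'C2': (-1.9716, 0.8823, 0.2911),
        'N3': (-2.2764, 2.0929, 0.7072),
        'C4': (-1.3213, 2.9674, 1.0035),
    },
    'C': {
        'P': (1.3777, 8.0736, 3.7836),
        'OP1': (0.9842, 9.4992, 3.7800),
        'OP2': (2.8157, 7.9150, 4.4884),
        "O5'": (0.2844, 7.2171, 4.5970),
        "C5'": (-0.1971, 6.2054, 3.7126),
        "C4'": (-1.7074, 6.3607, 3.5348),
        "O4'": (-2.0602, 6.4245, 2.1416),
        "C3'": (-2.4598, 5.1638, 4.1492),
        "O3'": (-3.3707, 5.6067, 5.1579),
        "C2'": (-3.2324, 4.5469, 2.9601),
        "O2'": (-4.5877, 4.9999, 2.9551),
        "C1'": (-2.4652, 5.1020, 1.7384),
        'N1': (-1.2989, 4.2652, 1.4470),
        'C2': (-1.4723, 3.0039, 1.0163),
        'O2': (-2.6028, 2.5683, 0.8724),
        'N3': (-0.4298, 2.2203, 0.7437),
        'C4': (0.8099, 2.6680, 0.8920),
        'N4': (1.8790, 1.8508, 0.6082),
        'C5': (1.0254, 3.9850, 1.3468),
        'C6': (-0.0445, 4.7704, 1.6131),
    },
    'G': {
        'P': (1.3777, 8.0736, 3.7836),
        'OP1': (0.9842, 9.4992, 3.7800),
        'OP2': (2.8157, 7.9150, 4.4884),
        "O5'": (0.2844, 7.2171, 4.5970),
        "C5'": (-0.1971, 6.2054, 3.7126),
        "C4'": (-1.7074, 6.3607, 3.5348),
        "O4'": (-2.0602, 6.4245, 2.1416),
        "C3'": (-2.4598, 5.1638, 4.1492),
        "O3'": (-3.3707, 5.6067, 5.1579),
        "C2'": (-3.2324, 4.5469, 2.9601),
        "O2'": (-4.5877, 4.9999, 2.9551),
        "C1'": (-2.4652, 5.1020, 1.7384),
        'N9': (-1.2991, 4.2653, 1.4472),
        'C8': (0.0086, 4.6353, 1.5697),
        'N7': (0.7812, 3.6457, 1.2275),
        'C5': (0.0175, 2.5853, 0.8663),
        'C6': (0.3018, 1.2752, 0.4153),
        'O6': (1.4532, 0.8973, 0.2810),
        'N1': (-0.7339, 0.4520, 0.1431),
        'C2': (-2.0160, 0.8880, 0.2905),
        'N2': (-3.0482, 0.0315, -0.0003),
        'N3': (-2.2934, 2.1022, 0.7085),
        'C4': (-1.3199, 2.9711, 1.0036),
    },
    'U': {
        'P': (1.3777, 8.0736, 3.7836),
        'OP1': (0.9842, 9.4992, 3.7800),
        'OP2': (2.8157, 7.9150, 4.4884),
        "O5'": (0.2844, 7.2171, 4.5970),
        "C5'": (-0.1971, 6.2054, 3.7126),
        "C4'": (-1.7074, 6.3607, 3.5348),
        "O4'": (-2.0602, 6.4245, 2.1416),
        "C3'": (-2.4598, 5.1638, 4.1492),
        "O3'": (-3.3707, 5.6067, 5.1579),
        "C2'": (-3.2324, 4.5469, 2.9601),
        "O2'": (-4.5877, 4.9999, 2.9551),
        "C1'": (-2.4652, 5.1020, 1.7384),
        'N1': (-1.2990, 4.2652, 1.4475),
        'C2': (-1.4750, 3.0036, 1.0202),
        'O2': (-2.6011, 2.5713, 0.8745),
        'N3': (-0.4199, 2.2145, 0.7411),
        'C4': (0.8362, 2.6790, 0.8981),
        'O4': (1.7906, 1.9637, 0.6507),
        'C5': (1.0343, 4.0040, 1.3522),
        'C6': (-0.0412, 4.7756, 1.6193),
    },
}
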