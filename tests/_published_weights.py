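"""The published per-study weight lookup table (two-decimal study counts).

Keys are sample sizes (per group for the two-sample design); values are the
printed dataset counts. One-sample spans n = 5..38, two-sample n = 5..69,
both plateauing at the 1.25 cap.
"""

ONE_SAMPLE_COUNTS = {
    5: 0.04, 6: 0.07, 7: 0.11, 8: 0.16, 9: 0.23, 10: 0.30, 11: 0.37,
    12: 0.45, 13: 0.53, 14: 0.61, 15: 0.69, 16: 0.76, 17: 0.83, 18: 0.89,
    19: 0.94, 20: 0.99, 21: 1.03, 22: 1.07, 23: 1.10, 24: 1.13, 25: 1.15,
    26: 1.17, 27: 1.18, 28: 1.20, 29: 1.21, 30: 1.22, 31: 1.22, 32: 1.23,
    33: 1.23, 34: 1.24, 35: 1.24, 36: 1.24, 37: 1.24, 38: 1.25,
}

TWO_SAMPLE_COUNTS = {
    5: 0.03, 6: 0.05, 7: 0.07, 8: 0.10, 9: 0.13, 10: 0.16, 11: 0.19,
    12: 0.23, 13: 0.27, 14: 0.31, 15: 0.35, 16: 0.39, 17: 0.44, 18: 0.48,
    19: 0.52, 20: 0.56, 21: 0.60, 22: 0.64, 23: 0.68, 24: 0.72, 25: 0.76,
    26: 0.79, 27: 0.83, 28: 0.86, 29: 0.89, 30: 0.92, 31: 0.94, 32: 0.97,
    33: 0.99, 34: 1.01, 35: 1.03, 36: 1.05, 37: 1.07, 38: 1.09, 39: 1.10,
    40: 1.12, 41: 1.13, 42: 1.14, 43: 1.15, 44: 1.16, 45: 1.17, 46: 1.18,
    47: 1.19, 48: 1.19, 49: 1.20, 50: 1.20, 51: 1.21, 52: 1.21, 53: 1.22,
    54: 1.22, 55: 1.22, 56: 1.23, 57: 1.23, 58: 1.23, 59: 1.23, 60: 1.24,
    61: 1.24, 62: 1.24, 63: 1.24, 64: 1.24, 65: 1.24, 66: 1.24, 67: 1.24,
    68: 1.24, 69: 1.25,
}
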