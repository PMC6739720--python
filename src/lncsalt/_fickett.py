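"""Fickett TESTCODE lookup tables.

Probability rows are indexed from the lowest parameter bin (index 0) to the
highest (index 9). Position-parameter bin edges run 1.1..1.9 in steps of 0.1;
content bin edges run 0.17..0.33 in steps of 0.02.
"""

POSITION_PROB = {
    "A": [0.22, 0.20, 0.34, 0.45, 0.68, 0.58, 0.93, 0.84, 0.68, 0.94],
    "C": [0.23, 0.30, 0.33, 0.51, 0.48, 0.66, 0.81, 0.70, 0.70, 0.80],
    "G": [0.08, 0.08, 0.16, 0.27, 0.48, 0.53, 0.64, 0.74, 0.88, 0.90],
    "T": [0.09, 0.09, 0.20, 0.54, 0.44, 0.69, 0.68, 0.91, 0.97, 0.97],
}

CONTENT_PROB = {
    "A": [0.21, 0.81, 0.65, 0.67, 0.49, 0.62, 0.55, 0.44, 0.49, 0.28],
    "C": [0.31, 0.39, 0.44, 0.43, 0.59, 0.59, 0.64, 0.51, 0.64, 0.82],
    "G": [0.29, 0.33, 0.41, 0.41, 0.73, 0.64, 0.64, 0.47, 0.54, 0.40],
    "T": [0.58, 0.51, 0.69, 0.56, 0.75, 0.55, 0.40, 0.39, 0.24, 0.28],
}

POSITION_WEIGHT = {"A": 0.26, "C": 0.18, "G": 0.31, "T": 0.33}
CONTENT_WEIGHT = {"A": 0.11, "C": 0.12, "G": 0.15, "T": 0.14}

POSITION_EDGE_START = 1.1  # first bin is parameter < 1.1
POSITION_EDGE_STEP = 0.1
CONTENT_EDGE_START = 0.17
CONTENT_EDGE_STEP = 0.02
N_BINS = 10


def position_bin(param: float) -> int:
    if param < POSITION_EDGE_START:
        return 0
    idx = int((param - POSITION_EDGE_START) / POSITION_EDGE_STEP) + 1
    return min(idx, N_BINS - 1)


def content_bin(fraction: float) -> int:
    if fraction < CONTENT_EDGE_START:
        return 0
    idx = int((fraction - CONTENT_EDGE_START) / CONTENT_EDGE_STEP) + 1
    return min(idx, N_BINS - 1)


def score_bounds() -> tuple[float, float]:
    """Min/max achievable TESTCODE score given the packaged tables."""
    lo = sum(POSITION_WEIGHT[b] * min(POSITION_PROB[b]) for b in "ACGT")
    lo += sum(CONTENT_WEIGHT[b] * min(CONTENT_PROB[b]) for b in "ACGT")
    hi = sum(POSITION_WEIGHT[b] * max(POSITION_PROB[b]) for b in "ACGT")
    hi += sum(CONTENT_WEIGHT[b] * max(CONTENT_PROB[b]) for b in "ACGT")
    return lo, hi
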