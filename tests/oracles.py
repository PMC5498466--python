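"""Independent oracle implementations used only by tests.

These deliberately avoid the package's code paths: a naive quadratic-space
Smith-Waterman DP, a grid-search isoelectric point, and a hand-written
residue mass table. Expected values frozen in the tests were produced by
these oracles before the implementation was written.
"""

import numpy as np
from Bio.Align import substitution_matrices

_B62 = substitution_matrices.load("BLOSUM62")


def _score(x: str, y: str) -> int:
    if x == "X" or y == "X":
        return 0
    return int(_B62[x, y])


def sw_naive(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    """Naive affine-gap Smith-Waterman; gap of length k costs open + k*extend."""
    n, m = len(a), len(b)
    NEG = -(10 ** 9)
    H = [[0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_extend, E[i - 1][j] - gap_extend)
            F[i][j] = max(H[i][j - 1] - gap_open - gap_extend, F[i][j - 1] - gap_extend)
            H[i][j] = max(0, H[i - 1][j - 1] + _score(a[i - 1], b[j - 1]),
                          E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return best


ORACLE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
ORACLE_WATER = 18.01528

ORACLE_PKA = {
    "Nterm": 8.6, "Cterm": 3.6, "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}


def mass_sum(seq: str) -> float:
    return sum(ORACLE_RESIDUE_MASS[r] for r in seq) + ORACLE_WATER


def charge_oracle(seq: str, ph: float) -> float:
    t = ORACLE_PKA
    c = 1 / (1 + 10 ** (ph - t["Nterm"])) - 1 / (1 + 10 ** (t["Cterm"] - ph))
    for r in seq:
        if r in "KRH":
            c += 1 / (1 + 10 ** (ph - t[r]))
        elif r in "DECY":
            c -= 1 / (1 + 10 ** (t[r] - ph))
    return c


def grid_pi(seq: str, step: float = 0.001) -> float:
    """Exhaustive grid search for the pH of minimum |charge| on [0, 14]."""
    grid = np.arange(0.0, 14.0 + step / 2, step)
    charges = np.abs([charge_oracle(seq, ph) for ph in grid])
    return float(grid[int(np.argmin(charges))])


def random_protein(rng, length: int) -> str:
    return "".join(rng.choice(list("ACDEFGHIKLMNPQRSTVWY"), size=length))
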