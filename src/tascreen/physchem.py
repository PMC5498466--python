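"""Sequence-derived protein properties: length, mass, isoelectric point.

Masses are average (not monoisotopic) residue masses plus one water,
matching standard proteomics calculators. Charge follows the
Henderson-Hasselbalch sum over termini and ionizable side chains; free
cysteines are assumed (no disulfide correction). Two pKa sets ship: the
EMBOSS values (default) and a Bjellqvist/ExPASy-style set.
"""

from __future__ import annotations

from dataclasses import dataclass

#: average residue masses in daltons (residue = amino acid minus water)
AVERAGE_RESIDUE_MASS = {
    "G": 57.0519, "A": 71.0788, "S": 87.0782, "P": 97.1167, "V": 99.1326,
    "T": 101.1051, "C": 103.1388, "L": 113.1594, "I": 113.1594, "N": 114.1038,
    "D": 115.0886, "Q": 128.1307, "K": 128.1741, "E": 129.1155, "M": 131.1926,
    "H": 137.1411, "F": 147.1766, "R": 156.1875, "Y": 163.1760, "W": 186.2132,
}
WATER_MASS = 18.01528

PKA_TABLES = {
    "EMBOSS": {
        "Nterm": 8.6, "Cterm": 3.6,
        "K": 10.8, "R": 12.5, "H": 6.5,
        "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
    },
    "Bjellqvist": {
        "Nterm": 7.5, "Cterm": 3.55,
        "K": 10.0, "R": 12.0, "H": 5.98,
        "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0,
    },
}

POSITIVE_RESIDUES = "KRH"
NEGATIVE_RESIDUES = "DECY"


@dataclass(frozen=True)
class PhyschemSummary:
    gene_id: str
    length_aa: int
    mw_da: float
    pi: float
    net_charge_ph7: float


def average_mass(seq: str) -> float:
    """Average molecular mass in daltons: residue masses plus one water.

    X is disallowed here because an ambiguous residue has no defined mass.
    """
    if not seq:
        raise ValueError("cannot compute mass of an empty sequence")
    try:
        return sum(AVERAGE_RESIDUE_MASS[r] for r in seq) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"residue {exc.args[0]!r} has no defined average mass") from exc


def charge_at_ph(seq: str, ph: float, pka_table: str = "EMBOSS") -> float:
    """Net protein charge at a given pH (Henderson-Hasselbalch sum).

    Positive groups (N-terminus, K, R, H) contribute +1/(1+10^(pH-pKa));
    negative groups (C-terminus, D, E, C, Y) contribute -1/(1+10^(pKa-pH)).
    """
    if not seq:
        raise ValueError("cannot compute charge of an empty sequence")
    try:
        pka = PKA_TABLES[pka_table]
    except KeyError:
        raise ValueError(
            f"unknown pKa table {pka_table!r}; available: {sorted(PKA_TABLES)}"
        ) from None
    charge = 1.0 / (1.0 + 10 ** (ph - pka["Nterm"]))
    charge -= 1.0 / (1.0 + 10 ** (pka["Cterm"] - ph))
    for r in seq:
        if r in POSITIVE_RESIDUES:
            charge += 1.0 / (1.0 + 10 ** (ph - pka[r]))
        elif r in NEGATIVE_RESIDUES:
            charge -= 1.0 / (1.0 + 10 ** (pka[r] - ph))
    return charge


def isoelectric_point(
    seq: str,
    pka_table: str = "EMBOSS",
    tolerance: float = 1e-4,
    max_iterations: int = 100,
) -> float:
    """pH of zero net charge, found by bisection on [0, 14].

    Charge is strictly decreasing in pH, positive at pH 0 (free N-terminus)
    and negative at pH 14 (free C-terminus), so a unique root exists.
    """
    lo, hi = 0.0, 14.0
    mid = 7.0
    for _ in range(max_iterations):
        mid = (lo + hi) / 2.0
        c = charge_at_ph(seq, mid, pka_table)
        if abs(c) < tolerance:
            return mid
        if c > 0:
            lo = mid
        else:
            hi = mid
    return mid


def pi_asymmetry(
    toxin: PhyschemSummary,
    antitoxin: PhyschemSummary,
    basic_threshold: float = 7.0,
    acidic_threshold: float = 7.0,
) -> bool:
    """True iff the toxin is basic and the antitoxin acidic (strict)."""
    return toxin.pi > basic_threshold and antitoxin.pi < acidic_threshold


def summarize(gene_id: str, seq: str, pka_table: str = "EMBOSS") -> PhyschemSummary:
    return PhyschemSummary(
        gene_id=gene_id,
        length_aa=len(seq),
        mw_da=average_mass(seq),
        pi=isoelectric_point(seq, pka_table),
        net_charge_ph7=charge_at_ph(seq, 7.0, pka_table),
    )
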