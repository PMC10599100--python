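"""Protein physicochemical properties.

Length, average molecular weight, theoretical isoelectric point and a
qualitative acidic/neutral/basic call — the property-table columns used
to characterize WxLIP proteins (which range from acidic pI ~5–7 in
*Enterococcus* to strongly basic pI 8–11 in *L. plantarum* and
*L. monocytogenes*).

The pI is the pH at which the Henderson–Hasselbalch net charge crosses
zero; the charge is strictly decreasing in pH, so bisection finds the
unique root. The default side-chain/terminal pKa set is the EMBOSS one;
the table is pluggable because different tools (e.g. ProtParam) use
slightly different sets, typically shifting pI by a few tenths of a pH
unit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

#: Average (not monoisotopic) residue masses, Da.
RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}
WATER_MASS = 18.0153
#: X contributes the mean residue mass.
MEAN_RESIDUE_MASS = sum(RESIDUE_MASS.values()) / len(RESIDUE_MASS)


@dataclass(frozen=True)
class PkaTable:
    """Ionizable-group pKa values (EMBOSS defaults)."""

    nterm: float = 8.6
    cterm: float = 3.6
    D: float = 3.9
    E: float = 4.1
    C: float = 8.5
    Y: float = 10.1
    H: float = 6.5
    K: float = 10.8
    R: float = 12.5


EMBOSS_PKA = PkaTable()

POSITIVE_RESIDUES = ("K", "R", "H")
NEGATIVE_RESIDUES = ("D", "E", "C", "Y")


@dataclass(frozen=True)
class PhyschemProfile:
    protein_id: str
    length: int
    mw: float  # Da, average isotopic
    pi: float
    acidity: str  # acidic | neutral | basic


def molecular_weight(sequence: str) -> float:
    """Average molecular weight in Da: residue masses plus one water."""
    if not sequence:
        raise ValueError("empty sequence")
    total = WATER_MASS
    for aa in sequence.upper():
        total += RESIDUE_MASS.get(aa, MEAN_RESIDUE_MASS)
    return total


def net_charge(sequence: str, pH: float, pka: PkaTable = EMBOSS_PKA) -> float:
    """Henderson–Hasselbalch net charge at the given pH.

    Positive groups (N-terminus, K, R, H) contribute
    1 / (1 + 10**(pH - pKa)); negative groups (C-terminus, D, E, C, Y)
    contribute −1 / (1 + 10**(pKa - pH)).
    """
    seq = sequence.upper()
    charge = 1.0 / (1.0 + 10.0 ** (pH - pka.nterm))
    charge -= 1.0 / (1.0 + 10.0 ** (pka.cterm - pH))
    for aa in POSITIVE_RESIDUES:
        n = seq.count(aa)
        if n:
            charge += n / (1.0 + 10.0 ** (pH - getattr(pka, aa)))
    for aa in NEGATIVE_RESIDUES:
        n = seq.count(aa)
        if n:
            charge -= n / (1.0 + 10.0 ** (getattr(pka, aa) - pH))
    return charge


def isoelectric_point(
    sequence: str, pka: PkaTable = EMBOSS_PKA, tol: float = 1e-4
) -> float:
    """Theoretical pI by bisection on the monotone net-charge curve."""
    if not sequence:
        raise ValueError("empty sequence")
    lo, hi = 0.0, 14.0
    while hi - lo > 1e-6:
        mid = (lo + hi) / 2.0
        q = net_charge(sequence, mid, pka)
        if abs(q) < tol:
            return mid
        if q > 0:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2.0


def acidity_call(pi: float) -> str:
    """Qualitative call: acidic below pH 6.5, basic above 7.5."""
    if not (0 < pi < 14):
        raise ValueError("pI out of range")
    if pi < 6.5:
        return "acidic"
    if pi > 7.5:
        return "basic"
    return "neutral"


def physchem_profile(
    protein_id: str, sequence: str, pka: PkaTable = EMBOSS_PKA
) -> PhyschemProfile:
    pi = isoelectric_point(sequence, pka)
    return PhyschemProfile(
        protein_id=protein_id,
        length=len(sequence),
        mw=molecular_weight(sequence),
        pi=pi,
        acidity=acidity_call(pi),
    )
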