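"""Monoisotopic mass constants for peptide m/z arithmetic.

All values in Daltons. Residue masses are the standard monoisotopic
masses of amino-acid residues (i.e. the free amino acid minus water).
Heavy-label deltas correspond to fully 13C/15N-labeled C-terminal
lysine (13C6 15N2) and arginine (13C6 15N4).
"""

from __future__ import annotations

#: Monoisotopic residue masses, Da.
RESIDUE_MASSES: dict[str, float] = {
    "G": 57.021464,
    "A": 71.037114,
    "S": 87.032028,
    "P": 97.052764,
    "V": 99.068414,
    "T": 101.047679,
    "C": 103.009185,
    "L": 113.084064,
    "I": 113.084064,
    "N": 114.042927,
    "D": 115.026943,
    "Q": 128.058578,
    "K": 128.094963,
    "E": 129.042593,
    "M": 131.040485,
    "H": 137.058912,
    "F": 147.068414,
    "R": 156.101111,
    "Y": 163.063329,
    "W": 186.079313,
}

#: Canonical 20-letter amino-acid alphabet.
CANONICAL_RESIDUES = frozenset(RESIDUE_MASSES)

WATER = 18.0105646863
PROTON = 1.00727646688

#: Mass shift of a 13C6 15N2 heavy lysine relative to light lysine.
HEAVY_K_DELTA = 8.014199
#: Mass shift of a 13C6 15N4 heavy arginine relative to light arginine.
HEAVY_R_DELTA = 10.008269

#: Monoisotopic deltas of the supported variable/fixed modifications.
MODIFICATION_DELTAS: dict[str, float] = {
    "carbamidomethyl-C": 57.021464,
    "oxidation-M": 15.994915,
    "acetyl-Nterm": 42.010565,
}

#: Maximum number of modifications tolerated on a single peptide.
MAX_MODIFICATIONS_PER_PEPTIDE = 3
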