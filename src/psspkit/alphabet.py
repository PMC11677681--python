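"""Residue and secondary-structure alphabets.

The residue alphabet is the 20 standard amino acids plus ``X``, the
catch-all for non-standard residues (B, J, O, U, Z and anything else).
Secondary structure uses the DSSP 8-state convention (H, G, I, E, B, T,
S, L) and its standard 3-state reduction: H/G/I -> helix (H), E/B ->
strand (E), T/S/L -> coil (C).
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWYX"
"""Ordered 21-letter residue alphabet (20 standard + X)."""

SS8: str = "HGIEBTSL"
"""Ordered DSSP 8-state categories."""

SS3: str = "HEC"
"""Ordered 3-state categories: helix, strand, coil."""

AA_INDEX = {a: i for i, a in enumerate(AMINO_ACIDS)}
SS8_INDEX = {s: i for i, s in enumerate(SS8)}
SS3_INDEX = {s: i for i, s in enumerate(SS3)}

_SS8_TO_SS3 = {"H": "H", "G": "H", "I": "H",
               "E": "E", "B": "E",
               "T": "C", "S": "C", "L": "C"}

X_INDEX = AA_INDEX["X"]


class LabelError(ValueError):
    """Raised for malformed residue or secondary-structure strings."""


def normalize_residue(letter: str) -> str:
    """Map a residue letter to the 21-letter alphabet (non-standard -> X)."""
    u = letter.upper()
    return u if u in AA_INDEX else "X"


def normalize_sequence(sequence: str) -> str:
    """Upper-case a residue string and replace non-standard letters by X."""
    return "".join(normalize_residue(c) for c in sequence)


def map_ss8_to_ss3(ss8_string: str) -> str:
    """Reduce an 8-state label string to 3 states (H/G/I->H, E/B->E, T/S/L->C).

    Raises
    ------
    LabelError
        If a character is not one of the eight DSSP states; the message
        names the offending position (1-based) and character.
    """
    out = []
    for pos, ch in enumerate(ss8_string):
        try:
            out.append(_SS8_TO_SS3[ch])
        except KeyError:
            raise LabelError(
                f"unknown 8-state label {ch!r} at position {pos + 1}"
            ) from None
    return "".join(out)
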