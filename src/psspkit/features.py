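"""Per-residue feature encoders."""

from __future__ import annotations

from typing import Optional

import numpy as np

from .alphabet import AA_INDEX, AMINO_ACIDS, normalize_sequence
from .physchem import PhyschemTable, load_physchem_table
from .records import FeatureBundle, ProteinRecord


def one_hot_encode(sequence: str) -> np.ndarray:
    """Encode a residue string as an L x 21 one-hot matrix.

    Non-standard letters land on the X column.  Each row has exactly one 1.
    """
    if len(sequence) == 0:
        raise ValueError("cannot one-hot encode an empty sequence")
    seq = normalize_sequence(sequence)
    out = np.zeros((len(seq), len(AMINO_ACIDS)))
    idx = [AA_INDEX[c] for c in seq]
    out[np.arange(len(seq)), idx] = 1.0
    return out


def physchem_encode(sequence: str, table: Optional[PhyschemTable] = None) -> np.ndarray:
    """Encode a residue string as an L x 7 matrix of physicochemical descriptors."""
    if table is None:
        table = load_physchem_table()
    seq = normalize_sequence(sequence)
    missing = sorted({c for c in seq if c not in table})
    if missing:
        raise KeyError(f"physicochemical table missing letters {missing}")
    return np.stack([table[c] for c in seq]) if seq else np.zeros((0, 7))


def build_bundle(
    record: ProteinRecord,
    *,
    pssm: Optional[np.ndarray] = None,
    hmm: Optional[np.ndarray] = None,
    embedding: Optional[np.ndarray] = None,
    hta_encoding: Optional[np.ndarray] = None,
    physchem_table: Optional[PhyschemTable] = None,
    with_physchem: bool = True,
) -> FeatureBundle:
    """Assemble a FeatureBundle for one record from whatever channels exist."""
    return FeatureBundle(
        one_hot=one_hot_encode(record.sequence),
        pssm=pssm,
        hmm=hmm,
        physchem=(physchem_encode(record.sequence, physchem_table)
                  if with_physchem else None),
        embedding=embedding,
        hta_encoding=hta_encoding,
    )
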