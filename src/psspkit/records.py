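"""Per-chain records and per-residue feature bundles."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .alphabet import AA_INDEX, SS8_INDEX, normalize_sequence


@dataclass
class ProteinRecord:
    """One protein chain: sequence plus optional per-residue tracks.

    All optional tracks, when present, must have the same length as the
    sequence.  The sequence is normalized on construction (upper case,
    non-standard letters replaced by X).
    """

    id: str
    sequence: str
    ss8: Optional[str] = None
    rsa: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if len(self.sequence) == 0:
            raise ValueError(f"record {self.id!r}: empty sequence")
        self.sequence = normalize_sequence(self.sequence)
        L = len(self.sequence)
        if self.ss8 is not None:
            if len(self.ss8) != L:
                raise ValueError(
                    f"record {self.id!r}: ss8 length {len(self.ss8)} "
                    f"!= sequence length {L}"
                )
            bad = set(self.ss8) - set(SS8_INDEX)
            if bad:
                raise ValueError(
                    f"record {self.id!r}: invalid ss8 letters {sorted(bad)}"
                )
        if self.rsa is not None:
            self.rsa = np.asarray(self.rsa, dtype=float)
            if self.rsa.shape != (L,):
                raise ValueError(
                    f"record {self.id!r}: rsa length {self.rsa.shape} "
                    f"!= sequence length {L}"
                )

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def aa_indices(self) -> np.ndarray:
        return np.fromiter(
            (AA_INDEX[c] for c in self.sequence), dtype=np.int64,
            count=len(self.sequence),
        )


@dataclass
class FeatureBundle:
    """Per-residue feature matrices for one chain, all sharing rows L.

    ``one_hot`` is always present (L x 21); the profile, physicochemical,
    language-model embedding and autoencoder-encoding channels are optional.
    """

    one_hot: np.ndarray
    pssm: Optional[np.ndarray] = None            # L x 20
    hmm: Optional[np.ndarray] = None             # L x 30
    physchem: Optional[np.ndarray] = None        # L x 7
    embedding: Optional[np.ndarray] = None       # L x D
    hta_encoding: Optional[np.ndarray] = None    # L x 4

    _EXPECTED_COLS = {"one_hot": 21, "pssm": 20, "hmm": 30, "physchem": 7}

    def __post_init__(self) -> None:
        L = self.one_hot.shape[0]
        for name in ("one_hot", "pssm", "hmm", "physchem",
                     "embedding", "hta_encoding"):
            mat = getattr(self, name)
            if mat is None:
                continue
            mat = np.asarray(mat, dtype=float)
            setattr(self, name, mat)
            if mat.ndim != 2 or mat.shape[0] != L:
                raise ValueError(
                    f"{name}: expected shape ({L}, *), got {mat.shape}"
                )
            want = self._EXPECTED_COLS.get(name)
            if want is not None and mat.shape[1] != want:
                raise ValueError(
                    f"{name}: expected {want} columns, got {mat.shape[1]}"
                )
        rowsums = self.one_hot.sum(axis=1)
        if not np.allclose(rowsums, 1.0):
            raise ValueError("one_hot rows must each sum to 1")

    def __len__(self) -> int:
        return self.one_hot.shape[0]

    def channels(self, names: list[str]) -> np.ndarray:
        """Horizontally stack the named feature blocks (all must be present)."""
        mats = []
        for name in names:
            mat = getattr(self, name)
            if mat is None:
                raise ValueError(f"feature channel {name!r} enabled but missing")
            mats.append(mat)
        return np.concatenate(mats, axis=1)
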