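"""Physicochemical descriptor table and max-ASA lookup.

The default seven-descriptor table (sheet propensity, helix propensity,
isoelectric point, hydrophobicity, van der Waals volume, polarizability,
graph shape index) and the max-ASA normalization table are shipped as
data files and can be overridden with any file of the same layout.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Mapping

import numpy as np

N_DESCRIPTORS = 7

DESCRIPTOR_NAMES = (
    "sheet_prob", "helix_prob", "pI", "hydrophobicity",
    "vdw_volume", "polarizability", "graph_shape",
)


class PhyschemTable:
    """Per-residue-letter lookup of 7 real descriptors covering all 21 letters."""

    def __init__(self, values: Mapping[str, np.ndarray]):
        self._values = {}
        for aa, vec in values.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (N_DESCRIPTORS,):
                raise ValueError(
                    f"residue {aa!r}: expected {N_DESCRIPTORS} descriptors, "
                    f"got {vec.shape}"
                )
            self._values[aa] = vec

    def __getitem__(self, aa: str) -> np.ndarray:
        try:
            return self._values[aa]
        except KeyError:
            raise KeyError(
                f"physicochemical table has no entry for residue {aa!r}"
            ) from None

    def __contains__(self, aa: str) -> bool:
        return aa in self._values

    @property
    def letters(self) -> list[str]:
        return sorted(self._values)


def _read_table(path) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#") or line.startswith("aa\t"):
            continue
        fields = line.split()
        out[fields[0]] = np.array([float(x) for x in fields[1:]])
    return out


def load_physchem_table(path=None) -> PhyschemTable:
    """Load the 7-descriptor table (default: packaged literature scales)."""
    if path is None:
        path = resources.files("psspkit.data") / "physchem7.tsv"
    return PhyschemTable(_read_table(path))


def load_max_asa(path=None) -> dict[str, float]:
    """Load the per-letter maximum ASA table used for RSA normalization."""
    if path is None:
        path = resources.files("psspkit.data") / "max_asa.tsv"
    return {aa: float(v[0]) for aa, v in _read_table(path).items()}
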