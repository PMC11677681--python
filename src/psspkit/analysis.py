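"""Corpus-level statistics linking secondary structure to solvent exposure.

The association between DSSP category and burial (RSA thresholded at
0.15) is quantified with Cramér's V on the 2 x 8 contingency table; a
strong association is the rationale for treating burial prediction as an
auxiliary task alongside secondary-structure prediction.  The module
also tallies the segment-length distribution that motivates the choice
of convolution scales.
"""

from __future__ import annotations

import warnings
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import SS8
from .metrics import extract_segments
from .physchem import load_max_asa
from .records import ProteinRecord

RSA_THRESHOLD = 0.15

BURIED, EXPOSED = "buried", "exposed"


def rsa_from_asa(asa: np.ndarray, sequence: str,
                 max_asa: Optional[dict] = None) -> np.ndarray:
    """Relative solvent accessibility: ASA over the residue type's maximum.

    Ratios above 1 (possible with theoretical maxima) are clipped to 1.
    """
    if max_asa is None:
        max_asa = load_max_asa()
    asa = np.asarray(asa, dtype=float)
    if np.any(asa < 0):
        raise ValueError("ASA values must be non-negative")
    denom = []
    for c in sequence:
        m = max_asa.get(c)
        if m is None or m <= 0:
            raise ValueError(f"max-ASA table has no positive entry for {c!r}")
        denom.append(m)
    return np.clip(asa / np.array(denom), 0.0, 1.0)


def rsa_binarize(rsa: float, threshold: float = RSA_THRESHOLD) -> str:
    """Classify an RSA fraction as buried (rsa <= threshold) or exposed."""
    if not 0.0 <= rsa <= 1.0:
        raise ValueError(f"RSA {rsa} outside [0, 1]")
    return BURIED if rsa <= threshold else EXPOSED


def contingency_table(records: Iterable[ProteinRecord],
                      threshold: float = RSA_THRESHOLD) -> pd.DataFrame:
    """2 x 8 residue counts of (burial bin x DSSP category) over a corpus."""
    from .alphabet import SS8_INDEX
    counts = np.zeros((2, len(SS8)), dtype=np.int64)
    for rec in records:
        if rec.ss8 is None or rec.rsa is None:
            raise ValueError(f"record {rec.id!r} lacks ss8 or rsa track")
        rsa = np.asarray(rec.rsa, dtype=float)
        if np.any((rsa < 0) | (rsa > 1)):
            raise ValueError(f"record {rec.id!r}: RSA outside [0, 1]")
        exposed = (rsa > threshold).astype(np.int64)
        cats = np.fromiter((SS8_INDEX[s] for s in rec.ss8), dtype=np.int64,
                           count=len(rec.ss8))
        np.add.at(counts, (exposed, cats), 1)
    return pd.DataFrame(counts, index=[BURIED, EXPOSED], columns=list(SS8))


def cramers_v(table) -> float:
    """Cramér's V association coefficient of a count table, in [0, 1].

    Expected counts are the margin products over the grand total; rows or
    columns with zero margin are dropped (with a warning) before the
    chi-square sum.  Margins are always recomputed from the cells.
    """
    O = np.asarray(table, dtype=float)
    if O.ndim != 2 or np.any(O < 0):
        raise ValueError("contingency table must be a 2-D non-negative array")
    rows = O.sum(axis=1)
    cols = O.sum(axis=0)
    if np.any(rows == 0) or np.any(cols == 0):
        warnings.warn("dropping zero-margin rows/columns before Cramér's V")
        O = O[rows > 0][:, cols > 0]
        rows = O.sum(axis=1)
        cols = O.sum(axis=0)
    m, n = O.shape
    total = O.sum()
    if total <= 0 or min(m, n) < 2:
        raise ValueError(
            f"degenerate table ({m} x {n}, total {total}): V undefined"
        )
    E = np.outer(rows, cols) / total
    chi2 = ((O - E) ** 2 / E).sum()
    return float(np.sqrt(chi2 / (total * min(m - 1, n - 1))))


def expected_counts(table) -> pd.DataFrame:
    """Independence-model expected counts E_ij = sum_i * sum_j / sum."""
    O = np.asarray(table, dtype=float)
    E = np.outer(O.sum(axis=1), O.sum(axis=0)) / O.sum()
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(E, index=table.index, columns=table.columns)
    return pd.DataFrame(E)


DEFAULT_LENGTH_BINS = (1, 3, 5, 7, 9, 11, 16, 21, 31, np.inf)


def segment_length_histogram(records: Iterable[ProteinRecord],
                             bin_edges: Sequence[float] = DEFAULT_LENGTH_BINS,
                             ) -> pd.Series:
    """Counts of secondary-structure segment lengths per interval bin.

    ``bin_edges`` are inclusive lower bounds; bin i covers
    [edge_i, edge_{i+1}).  Total count equals the number of segments.
    """
    lengths = []
    for rec in records:
        if rec.ss8 is None:
            raise ValueError(f"record {rec.id!r} lacks ss8 labels")
        lengths.extend(len(s) for s in extract_segments(rec.ss8))
    edges = list(bin_edges)
    labels = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        labels.append(f"{int(lo)}+" if np.isinf(hi)
                      else f"{int(lo)}-{int(hi - 1)}" if hi - lo > 1
                      else f"{int(lo)}")
    counts = np.zeros(len(labels), dtype=int)
    for length in lengths:
        for i, (lo, hi) in enumerate(zip(edges[:-1], edges[1:])):
            if lo <= length < hi:
                counts[i] += 1
                break
    return pd.Series(counts, index=labels, name="segments")


def load_reference_contingency() -> pd.DataFrame:
    """Packaged large-scale buried/exposed x SS8 residue tally (~6M residues)."""
    path = resources.files("psspkit.data") / "ss_rsa_reference_counts.tsv"
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    df.columns = list(SS8)
    return df
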