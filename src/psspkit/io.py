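"""Readers and writers for the formats the pipeline touches.

FASTA parsing is delegated to Biopython; the label table, PSI-BLAST ASCII
PSSM and HH-suite ``.hhm`` layouts are plain-text dialects parsed here.
"""

from __future__ import annotations

import io as _io
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import SeqIO

from .records import ProteinRecord


class ParseError(ValueError):
    """Malformed input file; the message carries a line number where known."""


# ---------------------------------------------------------------- FASTA

def read_fasta(path) -> list[ProteinRecord]:
    """Read a FASTA file into records (ids up to first whitespace).

    Sequences are upper-cased and non-standard letters replaced by X
    (done by ProteinRecord).  Raises :class:`ParseError` for an empty
    file or sequence data appearing before the first header.
    """
    text = Path(path).read_text()
    stripped = text.strip()
    if not stripped:
        raise ParseError(f"{path}: empty FASTA file (line 1)")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip() == "":
            continue
        if not line.startswith(">"):
            raise ParseError(
                f"{path}: sequence data before first header (line {lineno})"
            )
        break
    records = []
    for rec in SeqIO.parse(_io.StringIO(text), "fasta"):
        records.append(ProteinRecord(id=rec.id, sequence=str(rec.seq)))
    return records


def write_fasta(records: Sequence[ProteinRecord], path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.id}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i:i + width] + "\n")


# ---------------------------------------------------------------- labels

def read_labels(path) -> list[ProteinRecord]:
    """Read a whitespace-separated label table: id, sequence, ss8 [, RSA...].

    One record per non-comment line.  Optional trailing fields are the
    per-residue RSA fractions (exactly L of them when present).  Track
    lengths are validated against the sequence.
    """
    records = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        fields = line.split()
        if len(fields) < 3:
            raise ParseError(
                f"{path}: line {lineno}: expected 'id sequence ss8 [rsa...]'"
            )
        rid, seq, ss8 = fields[0], fields[1], fields[2]
        rsa = None
        if len(fields) > 3:
            if len(fields) - 3 != len(seq):
                raise ParseError(
                    f"{path}: line {lineno}: record {rid!r} has "
                    f"{len(fields) - 3} RSA values for {len(seq)} residues"
                )
            rsa = np.array([float(x) for x in fields[3:]])
        try:
            records.append(ProteinRecord(id=rid, sequence=seq, ss8=ss8, rsa=rsa))
        except ValueError as exc:
            raise ParseError(f"{path}: line {lineno}: {exc}") from None
    return records


def write_labels(records: Sequence[ProteinRecord], path,
                 rsa_decimals: int = 6) -> None:
    with open(path, "w") as fh:
        fh.write("# id sequence ss8 [rsa per residue]\n")
        for rec in records:
            if rec.ss8 is None:
                raise ValueError(f"record {rec.id!r} has no ss8 labels")
            parts = [rec.id, rec.sequence, rec.ss8]
            if rec.rsa is not None:
                parts.extend(f"{v:.{rsa_decimals}f}" for v in rec.rsa)
            fh.write(" ".join(parts) + "\n")


# ---------------------------------------------------------------- PSSM

def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def read_pssm(path, *, sigmoid: bool = False) -> np.ndarray:
    """Read the 20 log-odds columns of a PSI-BLAST ASCII PSSM.

    Returns an L x 20 matrix in PSI-BLAST column order.  With
    ``sigmoid=True`` the log-odds are squashed through 1/(1+e^-x).
    """
    rows = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        fields = line.split()
        # residue rows start "index letter" then >= 20 numeric columns
        if len(fields) >= 22 and fields[0].isdigit() and len(fields[1]) == 1:
            try:
                vals = [float(x) for x in fields[2:22]]
            except ValueError:
                raise ParseError(
                    f"{path}: line {lineno}: non-numeric log-odds entry"
                ) from None
            rows.append(vals)
        elif fields and fields[0].isdigit() and len(fields) > 2 and len(fields[1]) == 1:
            raise ParseError(
                f"{path}: line {lineno}: residue row has {len(fields) - 2} "
                "columns, expected at least 20"
            )
    if not rows:
        raise ParseError(f"{path}: no PSSM residue rows found")
    mat = np.array(rows)
    return _sigmoid(mat) if sigmoid else mat


# ---------------------------------------------------------------- HHM

def read_hhm(path, *, dequantize: bool = False,
             sentinel: float = 0.0) -> np.ndarray:
    """Read an HH-suite ``.hhm`` profile into an L x 30 matrix.

    Per residue: 20 match-emission columns followed by the 10
    transition/diversity columns.  ``*`` entries map to ``sentinel``.
    With ``dequantize=True`` stored integers x become 2^(-x/1000)
    (HH-suite's quantization); diversity columns (Neff*) are stored
    pre-scaled by 1000 and are de-quantized as x/1000 instead.
    """
    lines = Path(path).read_text().splitlines()
    try:
        start = next(i for i, ln in enumerate(lines) if ln.startswith("HMM"))
    except StopIteration:
        raise ParseError(f"{path}: no HMM block found") from None
    if not any(ln.strip() == "//" for ln in lines[start:]):
        raise ParseError(f"{path}: missing terminating '//' record")

    def conv(tok: str, diversity: bool) -> float:
        if tok == "*":
            return sentinel
        x = float(tok)
        if not dequantize:
            return x
        return x / 1000.0 if diversity else float(2.0 ** (-x / 1000.0))

    rows = []
    i = start + 1
    while i < len(lines):
        line = lines[i].strip()
        if line == "//":
            break
        fields = line.split()
        # residue emission line: "<aa> <pos> <20 values> <pos>"
        if (len(fields) >= 22 and len(fields[0]) == 1
                and fields[0].isalpha() and fields[1].isdigit()):
            emis = [conv(t, False) for t in fields[2:22]]
            i += 1
            trans_fields = lines[i].split()
            if len(trans_fields) != 10:
                raise ParseError(
                    f"{path}: line {i + 1}: expected 10 transition columns, "
                    f"got {len(trans_fields)}"
                )
            # last 3 columns are Neff diversity values
            trans = [conv(t, k >= 7) for k, t in enumerate(trans_fields)]
            rows.append(emis + trans)
        i += 1
    if not rows:
        raise ParseError(f"{path}: no residue rows in HMM block")
    return np.array(rows)


# ---------------------------------------------------------------- matrices

def read_matrix(path) -> np.ndarray:
    """Read a whitespace-delimited numeric matrix (embeddings, encodings)."""
    mat = np.loadtxt(path, ndmin=2)
    return mat


def write_matrix(mat: np.ndarray, path, fmt: str = "%.6g") -> None:
    np.savetxt(path, np.asarray(mat), fmt=fmt)
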