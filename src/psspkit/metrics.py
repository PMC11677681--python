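"""Residue- and segment-level evaluation of secondary-structure predictions.

Q accuracy counts correctly classified residues.  SOV (segment overlap)
scores how well maximal single-category segments are placed, rewarding
overlap between observed and predicted segments of the same category with
an allowance ``delta`` for small boundary shifts.  Boundary evaluation
restricts Q to residues at segment boundaries (sequence ends, residues
whose two flanks disagree, and single-residue category switches between
agreeing flanks).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import SS3, SS8, map_ss8_to_ss3


@dataclass(frozen=True)
class Segment:
    """Maximal run of one category over [start, end) (0-based, half-open)."""

    category: str
    start: int
    end: int

    def __len__(self) -> int:
        return self.end - self.start


def extract_segments(labels: str) -> list[Segment]:
    """Decompose a label string into its maximal single-category runs."""
    if len(labels) == 0:
        raise ValueError("empty label string")
    segments = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            segments.append(Segment(labels[start], start, i))
            start = i
    return segments


def _check_pair(pred: str, obs: str) -> None:
    if len(pred) != len(obs):
        raise ValueError(
            f"prediction length {len(pred)} != observation length {len(obs)}"
        )
    if len(obs) == 0:
        raise ValueError("empty labelings")


# ------------------------------------------------------------------ Q

def q_accuracy(pred: str, obs: str) -> float:
    """Percentage of residues whose predicted category matches the observed one."""
    _check_pair(pred, obs)
    correct = sum(p == o for p, o in zip(pred, obs))
    return 100.0 * correct / len(obs)


# ------------------------------------------------------------------ SOV

class SOVAccumulator:
    """Pools SOV numerator and normalizer over sequences.

    For each category, observed/predicted segment pairs that overlap
    contribute ``(minov + delta) / maxov * l(s1)`` to the numerator and
    ``l(s1)`` to the normalizer N; observed segments with no
    same-category overlap contribute ``l(s1)`` to N only.
    ``delta = min(maxov - minov, minov, floor(l(s1)/2), floor(l(s2)/2))``.
    """

    def __init__(self, states: str = SS8):
        self.states = states
        self.numerator = 0.0
        self.normalizer = 0

    def add(self, pred: str, obs: str) -> None:
        _check_pair(pred, obs)
        obs_segs = extract_segments(obs)
        pred_segs = extract_segments(pred)
        for cat in self.states:
            obs_c = [s for s in obs_segs if s.category == cat]
            pred_c = [s for s in pred_segs if s.category == cat]
            for s1 in obs_c:
                overlaps = [s2 for s2 in pred_c
                            if s2.start < s1.end and s1.start < s2.end]
                if not overlaps:
                    self.normalizer += len(s1)
                    continue
                for s2 in overlaps:
                    minov = min(s1.end, s2.end) - max(s1.start, s2.start)
                    maxov = max(s1.end, s2.end) - min(s1.start, s2.start)
                    delta = min(maxov - minov, minov,
                                len(s1) // 2, len(s2) // 2)
                    self.numerator += (minov + delta) / maxov * len(s1)
                    self.normalizer += len(s1)

    @property
    def value(self) -> float:
        if self.normalizer == 0:
            raise ValueError("SOV undefined: no observed segments accumulated")
        return 100.0 * self.numerator / self.normalizer


def sov(pred: str, obs: str, states: str = SS8) -> float:
    """Segment-overlap score of one prediction, in [0, 100]."""
    acc = SOVAccumulator(states)
    acc.add(pred, obs)
    return acc.value


# ------------------------------------------------------------ confusion

def confusion_matrix(pred: str, obs: str, states: str = SS8,
                     normalized: bool = False) -> pd.DataFrame:
    """Counts (or row-normalized rates) indexed observed x predicted."""
    _check_pair(pred, obs)
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)))
    for p, o in zip(pred, obs):
        counts[index[o], index[p]] += 1
    if normalized:
        sums = counts.sum(axis=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            counts = np.where(sums > 0, counts / np.where(sums == 0, 1, sums), 0.0)
    return pd.DataFrame(counts, index=list(states), columns=list(states))


# ------------------------------------------------------------- boundary

@dataclass
class BoundaryMask:
    """Per-residue boundary flags with the triggering type (1, 2 or 3)."""

    mask: np.ndarray   # bool, length L
    types: np.ndarray  # int, 0 where not a boundary residue


def boundary_mask(labels: str) -> BoundaryMask:
    """Mark boundary residues.

    Type 1: first or last residue of the chain.  For interior residues i:
    Type 2: the two flanking categories differ; Type 3: the flanks agree
    but residue i's own category differs from them.
    """
    if len(labels) == 0:
        raise ValueError("empty label string")
    L = len(labels)
    types = np.zeros(L, dtype=int)
    types[0] = 1
    types[L - 1] = 1
    for i in range(1, L - 1):
        if types[i]:
            continue
        if labels[i - 1] != labels[i + 1]:
            types[i] = 2
        elif labels[i] != labels[i - 1]:
            types[i] = 3
    return BoundaryMask(mask=types > 0, types=types)


def boundary_accuracy(pred: str, obs: str) -> float:
    """Q accuracy restricted to the boundary residues of the observed labeling."""
    _check_pair(pred, obs)
    mask = boundary_mask(obs).mask
    n = int(mask.sum())
    correct = sum(1 for i in np.flatnonzero(mask) if pred[i] == obs[i])
    return 100.0 * correct / n


# ------------------------------------------------------------ reporting

def evaluate(pairs: Iterable[tuple[str, str]], states: str = SS8) -> dict:
    """Pooled evaluation of (pred, obs) label-string pairs.

    Counts and SOV sums are pooled over all sequences (not averaged
    per sequence).  Returns Q, SOV, per-category recall, boundary
    accuracy and the confusion matrix; when ``states`` is the 8-state
    alphabet the 3-state metrics after mapping are included as well.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("no prediction/observation pairs to evaluate")
    correct = total = 0
    b_correct = b_total = 0
    sov_acc = SOVAccumulator(states)
    index = {s: i for i, s in enumerate(states)}
    counts = np.zeros((len(states), len(states)))
    for pred, obs in pairs:
        _check_pair(pred, obs)
        correct += sum(p == o for p, o in zip(pred, obs))
        total += len(obs)
        sov_acc.add(pred, obs)
        bm = boundary_mask(obs).mask
        b_total += int(bm.sum())
        b_correct += sum(1 for i in np.flatnonzero(bm) if pred[i] == obs[i])
        for p, o in zip(pred, obs):
            counts[index[o], index[p]] += 1
    recalls = {}
    for s in states:
        row = counts[index[s]]
        recalls[s] = float("nan") if row.sum() == 0 else 100.0 * row[index[s]] / row.sum()
    report = {
        "n_sequences": len(pairs),
        "n_residues": total,
        "q": 100.0 * correct / total,
        "sov": sov_acc.value,
        "boundary_accuracy": 100.0 * b_correct / b_total,
        "recall_per_category": recalls,
        "confusion": pd.DataFrame(counts, index=list(states), columns=list(states)),
    }
    if states == SS8:
        mapped = [(map_ss8_to_ss3(p), map_ss8_to_ss3(o)) for p, o in pairs]
        report["ss3"] = evaluate(mapped, states=SS3)
    return report


def format_report(report: dict, label: str = "SS8") -> str:
    """Render an evaluation report as plain text."""
    lines = [
        f"[{label}] sequences={report['n_sequences']} residues={report['n_residues']}",
        f"  Q   = {report['q']:.2f}%",
        f"  SOV = {report['sov']:.2f}%",
        f"  boundary Q = {report['boundary_accuracy']:.2f}%",
        "  per-category recall: "
        + "  ".join(f"{s}={v:.1f}" for s, v in report["recall_per_category"].items()
                    if v == v),
    ]
    if "ss3" in report:
        lines.append(format_report(report["ss3"], label="SS3"))
    return "\n".join(lines)
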