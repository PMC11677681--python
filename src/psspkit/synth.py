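"""Synthetic protein corpora with controllable structure statistics.

Chains are generated segment-wise: a first-order category chain (zero
self-transitions, so segments are maximal), per-category segment-length
distributions concentrated on short runs (most real segments are 1-11
residues), per-category amino-acid emission distributions, and a
per-category exposure probability that induces a tunable association
between secondary structure and burial.  The generator returns its own
bookkeeping (sampled segments, residue tallies) so downstream statistics
can be checked against ground truth.

This is a statistical emulation, not a biophysical model: residues are
conditionally independent given the category, and there is no
sequence-structure energetics.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .alphabet import AMINO_ACIDS, SS8
from .analysis import BURIED, EXPOSED, RSA_THRESHOLD, cramers_v
from .io import write_fasta, write_labels
from .records import ProteinRecord

N_CAT = len(SS8)
N_AA = len(AMINO_ACIDS)

# segment-level category weights: helix, strand and coil-like states common,
# pi-helix (I) rare
_CATEGORY_WEIGHTS = {
    "H": 0.26, "G": 0.05, "I": 0.003, "E": 0.21,
    "B": 0.02, "T": 0.14, "S": 0.09, "L": 0.23,
}

# mean segment length per category (geometric, truncated at max_segment_len)
_MEAN_LENGTHS = {
    "H": 6.0, "G": 3.0, "I": 4.0, "E": 4.0,
    "B": 1.3, "T": 2.5, "S": 1.8, "L": 3.0,
}

# residues favoured by each category in the default (noisy) emissions
_PREFERRED = {
    "H": "AELMQK", "G": "AGNDS", "I": "AELM", "E": "VIYFWT",
    "B": "VIYC", "T": "GPNDS", "S": "GPNSD", "L": "GPSDNK",
}


def _default_transitions() -> np.ndarray:
    w = np.array([_CATEGORY_WEIGHTS[c] for c in SS8])
    T = np.tile(w, (N_CAT, 1))
    np.fill_diagonal(T, 0.0)
    return T / T.sum(axis=1, keepdims=True)


def _default_length_dists(max_len: int) -> np.ndarray:
    dists = np.zeros((N_CAT, max_len))
    k = np.arange(1, max_len + 1)
    for i, c in enumerate(SS8):
        p = 1.0 / _MEAN_LENGTHS[c]
        probs = (1 - p) ** (k - 1) * p
        dists[i] = probs / probs.sum()
    return dists


def _default_emissions(sharpness: float = 0.6) -> np.ndarray:
    """Per-category 21-way residue distributions, biased toward preferred sets."""
    em = np.full((N_CAT, N_AA), (1.0 - sharpness) / 20.0)
    em[:, AMINO_ACIDS.index("X")] = 0.0  # X never emitted by default
    for i, c in enumerate(SS8):
        pref = _PREFERRED[c]
        for a in pref:
            em[i, AMINO_ACIDS.index(a)] += sharpness / len(pref)
    return em / em.sum(axis=1, keepdims=True)


def deterministic_emissions() -> np.ndarray:
    """One distinct residue per category (sequence readable off the labels)."""
    letters = "AGMVCPST"  # one per H,G,I,E,B,T,S,L
    em = np.zeros((N_CAT, N_AA))
    for i, a in enumerate(letters):
        em[i, AMINO_ACIDS.index(a)] = 1.0
    return em


def _default_p_exposed() -> np.ndarray:
    # helix/strand-like states lean buried, turns/bends/coil lean exposed
    return np.array([0.42, 0.55, 0.40, 0.33, 0.48, 0.66, 0.62, 0.64])


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic corpus generator.

    ``transitions`` rows must sum to 1 with a zero diagonal (segments are
    maximal); ``length_dists[c]`` is a distribution over lengths
    1..max_segment_len; ``emissions[c]`` a 21-way residue distribution;
    ``p_exposed[c]`` the probability a residue of category c is exposed
    (RSA > 0.15).
    """

    n_sequences: int = 200
    min_length: int = 30
    max_length: int = 60
    max_segment_len: int = 20
    transitions: np.ndarray = field(default_factory=_default_transitions)
    length_dists: np.ndarray = field(default_factory=lambda: _default_length_dists(20))
    emissions: np.ndarray = field(default_factory=_default_emissions)
    p_exposed: np.ndarray = field(default_factory=_default_p_exposed)
    continuous_rsa: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        self.transitions = np.asarray(self.transitions, dtype=float)
        self.length_dists = np.asarray(self.length_dists, dtype=float)
        self.emissions = np.asarray(self.emissions, dtype=float)
        self.p_exposed = np.asarray(self.p_exposed, dtype=float)
        if self.transitions.shape != (N_CAT, N_CAT):
            raise ValueError("transitions must be 8 x 8")
        if np.any(np.diag(self.transitions) != 0):
            raise ValueError("transitions must have a zero diagonal")
        if not np.allclose(self.transitions.sum(axis=1), 1.0):
            raise ValueError("transition rows must sum to 1")
        if self.length_dists.shape != (N_CAT, self.max_segment_len):
            raise ValueError("length_dists must be 8 x max_segment_len")
        if not np.allclose(self.length_dists.sum(axis=1), 1.0):
            raise ValueError("length distributions must sum to 1")
        if self.emissions.shape != (N_CAT, N_AA):
            raise ValueError("emissions must be 8 x 21")
        if not np.allclose(self.emissions.sum(axis=1), 1.0):
            raise ValueError("emission rows must sum to 1")
        if np.any((self.p_exposed < 0) | (self.p_exposed > 1)):
            raise ValueError("p_exposed entries must lie in [0, 1]")

    def stationary_category_freqs(self) -> np.ndarray:
        """Expected per-residue category frequencies (segment chain x mean length)."""
        vals, vecs = np.linalg.eig(self.transitions.T)
        k = int(np.argmin(np.abs(vals - 1.0)))
        pi = np.real(vecs[:, k])
        pi = np.abs(pi) / np.abs(pi).sum()
        mean_len = self.length_dists @ np.arange(1, self.max_segment_len + 1)
        p = pi * mean_len
        return p / p.sum()


@dataclass
class GeneratorTallies:
    """Ground-truth bookkeeping emitted alongside a generated corpus."""

    segments: list  # per record: list of (category, length) actually realized
    contingency: pd.DataFrame  # buried/exposed x SS8 residue counts
    length_counts: pd.DataFrame  # category x length counts


def generate_corpus(config: GeneratorConfig,
                    rng: Optional[np.random.Generator] = None,
                    ) -> tuple[list[ProteinRecord], GeneratorTallies]:
    """Sample a corpus of records with ss8 and RSA tracks, plus tallies."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    records = []
    all_segments = []
    cont = np.zeros((2, N_CAT), dtype=np.int64)  # rows: buried, exposed
    length_counts = np.zeros((N_CAT, config.max_segment_len), dtype=np.int64)
    init = config.stationary_category_freqs()
    trans_cum = np.cumsum(config.transitions, axis=1)
    len_cum = np.cumsum(config.length_dists, axis=1)
    aa_letters = np.array(list(AMINO_ACIDS))
    for n in range(config.n_sequences):
        target_len = int(rng.integers(config.min_length, config.max_length + 1))
        cats: list[int] = []
        lens: list[int] = []
        total = 0
        while total < target_len:
            if not cats:
                c = int(rng.choice(N_CAT, p=init))
            else:
                c = int(np.searchsorted(trans_cum[cats[-1]], rng.random(),
                                        side="right"))
            length = int(np.searchsorted(len_cum[c], rng.random(),
                                         side="right")) + 1
            length = min(length, target_len - total)
            cats.append(c)
            lens.append(length)
            total += length
        seq_parts, ss_parts, rsa_parts = [], [], []
        seg_record = []
        for c, length in zip(cats, lens):
            cat = SS8[c]
            seg_record.append((cat, length))
            length_counts[c, length - 1] += 1
            ss_parts.append(cat * length)
            aa_idx = rng.choice(N_AA, size=length, p=config.emissions[c])
            seq_parts.append("".join(aa_letters[aa_idx]))
            exposed = rng.random(length) < config.p_exposed[c]
            n_exp = int(exposed.sum())
            cont[1, c] += n_exp
            cont[0, c] += length - n_exp
            if config.continuous_rsa:
                u = rng.random(length)
                v = np.where(
                    exposed,
                    np.maximum(RSA_THRESHOLD + (1.0 - RSA_THRESHOLD) * u,
                               np.nextafter(RSA_THRESHOLD, 1.0)),
                    RSA_THRESHOLD * u,
                )
            else:
                v = exposed.astype(float)
            rsa_parts.append(v)
        records.append(ProteinRecord(
            id=f"synth{n:05d}",
            sequence="".join(seq_parts),
            ss8="".join(ss_parts),
            rsa=np.concatenate(rsa_parts),
        ))
        all_segments.append(seg_record)
    cont_df = pd.DataFrame(cont, index=[BURIED, EXPOSED], columns=list(SS8))
    len_df = pd.DataFrame(length_counts, index=list(SS8),
                          columns=range(1, config.max_segment_len + 1))
    return records, GeneratorTallies(all_segments, cont_df, len_df)


def calibrate_association(target_v: float,
                          base_config: Optional[GeneratorConfig] = None,
                          ) -> GeneratorConfig:
    """Adjust per-category exposure probabilities to hit a target Cramér's V.

    For a 2 x n table the expected V of this construction has the closed
    form V = sqrt(sum_c p_c (q_c - qbar)^2 / (qbar (1 - qbar))) where p_c
    are residue category frequencies and q_c the exposure probabilities.
    The spread of q_c around their mean is scaled to solve for the target.
    """
    if base_config is None:
        base_config = GeneratorConfig()
    if target_v < 0:
        raise ValueError("target_v must be non-negative")
    p = base_config.stationary_category_freqs()
    q = base_config.p_exposed.astype(float)
    qbar = float(p @ q)
    d = q - qbar
    d = d - (p @ d)  # enforce sum_c p_c d_c = 0 exactly
    if np.allclose(d, 0):
        d = np.array([-1.0, 0.5, -0.5, -1.0, 0.0, 1.0, 0.8, 1.0])
        d = d - (p @ d)
    denom = float(p @ d ** 2)
    t = target_v * np.sqrt(qbar * (1 - qbar) / denom)
    q_new = qbar + t * d
    if np.any((q_new < 0) | (q_new > 1)):
        raise ValueError(
            f"target V={target_v} not achievable around mean exposure {qbar:.3f}"
        )
    cfg = GeneratorConfig(
        n_sequences=base_config.n_sequences,
        min_length=base_config.min_length,
        max_length=base_config.max_length,
        max_segment_len=base_config.max_segment_len,
        transitions=base_config.transitions,
        length_dists=base_config.length_dists,
        emissions=base_config.emissions,
        p_exposed=q_new,
        continuous_rsa=base_config.continuous_rsa,
        seed=base_config.seed,
    )
    return cfg


def expected_association(config: GeneratorConfig) -> float:
    """Closed-form expected Cramér's V of a generated corpus."""
    p = config.stationary_category_freqs()
    q = config.p_exposed
    qbar = float(p @ q)
    return float(np.sqrt(p @ (q - qbar) ** 2 / (qbar * (1 - qbar))))


def write_corpus(records, out_dir, config: Optional[GeneratorConfig] = None) -> dict:
    """Write FASTA + label files (+ provenance when config given); return paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fasta = out / "corpus.fasta"
    labels = out / "corpus.labels"
    write_fasta(records, fasta)
    write_labels(records, labels)
    paths = {"fasta": str(fasta), "labels": str(labels)}
    if config is not None:
        prov = out / "provenance.yaml"
        with open(prov, "w") as fh:
            yaml.safe_dump({
                "n_sequences": config.n_sequences,
                "min_length": config.min_length,
                "max_length": config.max_length,
                "seed": config.seed,
                "p_exposed": [float(x) for x in config.p_exposed],
            }, fh)
        paths["provenance"] = str(prov)
    return paths
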