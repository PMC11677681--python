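"""Independent brute-force transcription of the segment-overlap score.

Written directly from the metric's definition, separately from the
library implementation, to serve as an oracle in tests.
"""

from __future__ import annotations


def runs(labels):
    """(category, set of positions) for each maximal run."""
    out = []
    i = 0
    while i < len(labels):
        j = i
        while j < len(labels) and labels[j] == labels[i]:
            j += 1
        out.append((labels[i], frozenset(range(i, j))))
        i = j
    return out


def sov_bruteforce(pred: str, obs: str, states: str) -> float:
    assert len(pred) == len(obs) and len(obs) > 0
    numerator = 0.0
    N = 0
    for cat in states:
        obs_runs = [r for c, r in runs(obs) if c == cat]
        pred_runs = [r for c, r in runs(pred) if c == cat]
        for s1 in obs_runs:
            pairs = [s2 for s2 in pred_runs if s1 & s2]
            if not pairs:
                N += len(s1)
                continue
            for s2 in pairs:
                minov = len(s1 & s2)
                maxov = len(s1 | s2)
                delta = min(maxov - minov, minov,
                            len(s1) // 2, len(s2) // 2)
                numerator += (minov + delta) / maxov * len(s1)
                N += len(s1)
    return 100.0 * numerator / N
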