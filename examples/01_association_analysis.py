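"""Quantify the association between secondary structure and burial.

Computes Cramér's V on a published 2x8 tally of ~6 million residues
(buried/exposed at RSA 0.15 x DSSP category), then calibrates the
synthetic generator to the same association strength and re-measures it
on a generated corpus.  A V around 0.2 means burial carries real but
far-from-deterministic information about the structural category —
the rationale for treating burial prediction as an auxiliary task.
"""

import psspkit as pk
from psspkit.analysis import expected_counts

table = pk.load_reference_contingency()
print("reference contingency table (counts):")
print(table)
print("\nexpected counts under independence:")
print(expected_counts(table).round(0))
v = pk.cramers_v(table)
print(f"\nCramér's V = {v:.4f}  (0 = independent, 1 = deterministic)")

base = pk.GeneratorConfig(n_sequences=2000, min_length=40, max_length=50,
                          seed=1)
cfg = pk.calibrate_association(v, base)
records, _ = pk.generate_corpus(cfg)
measured = pk.cramers_v(pk.contingency_table(records))
n = sum(len(r) for r in records)
print(f"\nsynthetic corpus calibrated to V={v:.4f}: "
      f"measured V = {measured:.4f} on {n} residues")
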