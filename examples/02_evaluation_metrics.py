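"""Score a secondary-structure prediction with Q, SOV and boundary accuracy.

Q counts correct residues; SOV scores segment placement (a small
boundary shift of an otherwise-found segment is forgiven); boundary
accuracy restricts Q to the hardest residues — sequence ends and
category switch points.
"""

from psspkit import evaluate, q_accuracy, sov
from psspkit.metrics import format_report

obs = "LLHHHHHHHHTTEEEEELLLHHHHHHSSLL"
good = "LHHHHHHHHHTTEEEEELLLHHHHHHSSLL"   # one boundary off by one
bad = "LLHHHHHHHHLLLLLLLLLLHHHHHHLLLL"    # strand segment missed

for name, pred in (("shifted boundary", good), ("missed strand", bad)):
    print(f"{name}: Q8 = {q_accuracy(pred, obs):.1f}%  "
          f"SOV8 = {sov(pred, obs):.1f}%")

print("\npooled report over both predictions:")
print(format_report(evaluate([(good, obs), (bad, obs)])))
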