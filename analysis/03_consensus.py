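#!/usr/bin/env python
"""Cross-check the seven delimitation methods by majority rule.

Candidate species are the true species of the simulation (standing in for the
morphology/phylogeny-derived candidates of a real study); a candidate is
accepted when strictly more than four of the seven methods return it as an
exact cluster. Writes results/03_decisions.tsv and the per-sequence
comparison table results/03_consensus_table.tsv.
"""

from pathlib import Path

from shdelim.consensus import assemble, decide
from shdelim.seqio import read_partition_table

base = Path(__file__).resolve().parent.parent
results = base / "results"

parts = read_partition_table(results / "02_partitions.tsv")
truth = read_partition_table(base / "data" / "truth.tsv")[0]

table = assemble(parts)
table.table.to_csv(results / "03_consensus_table.tsv", sep="\t",
                   index_label="sequence_id")

decisions = decide(parts, truth.cluster_sets(), cutoff=4)
with open(results / "03_decisions.tsv", "w") as fh:
    fh.write("candidate\tn_members\tsupport\tdecision\n")
    for d in sorted(decisions, key=lambda d: sorted(d.tips)[0]):
        name = sorted(d.tips)[0].rsplit("_", 1)[0]
        fh.write(f"{name}\t{len(d.tips)}\t{d.support}\t{d.decision}\n")

accepted = sum(d.decision == "accepted" for d in decisions)
print(f"{accepted}/{len(decisions)} candidate species accepted "
      f"(support > 4 of {len(parts)} methods)")
for d in sorted(decisions, key=lambda d: sorted(d.tips)[0]):
    print(f"  {sorted(d.tips)[0].rsplit('_', 1)[0]}: "
          f"support {d.support}/{len(parts)} -> {d.decision}")
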