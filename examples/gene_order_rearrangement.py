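"""Detecting a tRNA-cluster rearrangement as adjacency breakpoints.

Simulates a genome with the trnA/trnR swap inside the trnA-trnF cluster and
diffs its gene order against the unrearranged lepidopteran order.
"""

import mitocomp as mc

record, _ = mc.simulate_mitogenome(mc.conopomorpha_config(seed=1))
order = mc.extract_gene_order(record)

ancestral = mc.GeneOrder.from_signed_labels(
    [("-" if s == "-" else "") + n
     for n, _c, _l, s in mc.gene_plan("ancestral")]
).normalized("trnM").restrict(set(order.labels))

i = order.labels.index("trnR")
print("cluster in this genome: ", " ".join(order.labels[i:i + 6]))
j = ancestral.labels.index("trnA")
print("cluster in the reference:", " ".join(ancestral.labels[j:j + 6]))

report = mc.diff_orders(ancestral, order)
print(f"\nbreakpoints: {report.breakpoints}  "
      f"shared adjacencies: {report.shared_adjacencies}")
print(f"moved genes: {sorted(report.moved_genes)}")
print(f"classification: {sorted(report.classification)}")
print("\nTwo breakpoints and a one-gene removal certificate are the")
print("signature of an adjacent transposition (gene swap).")
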