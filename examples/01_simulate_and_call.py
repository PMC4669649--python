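"""Simulate an easy SNP panel and call it end to end.

Generates 500 samples at 20 common SNPs (MAF 0.2) with 100 known-genotype
QC samples, runs the two-stage caller with 600 augmentation subjects per
SNP, and scores the calls against the simulation truth.
"""

import augcall
from augcall.containers import RunConfig
from augcall.evaluation import GenotypeCounts, call_rate, concordance
from augcall.simulate import SimulationConfig, generate_panel

cfg = SimulationConfig(n_samples=500, n_snps=20, n_known=100, maf_spec=0.2, seed=31)
panel, known, truth = generate_panel(cfg)

calls = augcall.call_panel(panel, known, RunConfig(ratio=(2, 1), m=600, seed=31))

table = truth.as_known_table()
truth_list = [
    table.get(s, p) for s, p in zip(calls.calls["sample_id"], calls.calls["snp_id"])
]
counts = GenotypeCounts.from_calls(calls.calls["genotype"])
n_g1 = int((calls.snp_report["group"] == "G1").sum())

print(f"SNPs: {panel.n_snps} ({n_g1} G1 direct, {panel.n_snps - n_g1} G2 via reference)")
print(f"call rate: {100 * call_rate(counts):.2f}%")
print(f"accuracy vs truth: {100 * concordance(list(calls.calls['genotype']), truth_list):.2f}%")
# Call rate is the fraction of sample-SNP pairs receiving a genotype; accuracy
# is agreement with the simulated truth over the called pairs.
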