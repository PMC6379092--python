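"""Upstream-regulator over-representation on a differential signature.

Simulates the repressed-mitochondria study, derives the per-gene signature
(Welch test, raw p < 0.05), and asks which TFs in a signed TF->target
network have targets over-represented in it (Fisher, p < 0.01), with an
activation z summarising sign consistency.
"""

from mitoscreen import per_gene_tests, regulator_overlap
from mitoscreen.synthetic import ScenarioSpec, generate_scenario

sc = generate_scenario(ScenarioSpec(seed=1))
signature = per_gene_tests(sc.matrix, "WT", "KO")
print(f"signature: {len(signature)} of {len(sc.matrix.gene_ids)} genes at p < 0.05")

results = regulator_overlap(sc.network, signature, set(sc.matrix.gene_ids))
print(f"{'TF':8s} {'targets_in_sig':>14s} {'fisher_p':>10s} {'z':>6s}  significant")
for r in sorted(results, key=lambda r: r.fisher_p):
    z = f"{r.activation_z:6.2f}" if r.activation_z is not None else "    --"
    print(f"{r.tf:8s} {r.a:8d}/{r.a + r.b:<5d} {r.fisher_p:10.2e} {z}  {r.significant}")
print(
    "\nThe planted repressor's targets pile into the signature (tiny p, "
    "positive z = repressive edges agree with the down-regulation); decoy "
    "TFs with random targets stay non-significant."
)
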