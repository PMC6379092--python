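"""Organelle gene-set expression scoring on a simulated case/control study.

Simulates a 6v6 microarray-style experiment in which a 200-gene
mitochondrial list is repressed to 0.75x control, then scores every
organelle list: per-sample set averages normalized to the control mean,
Welch t-test between groups, Bonferroni adjustment over the list's genes.
"""

from mitoscreen import adjust_scores, control_normalize, organelle_score, percent_change
from mitoscreen.genelists import GeneList
from mitoscreen.synthetic import ScenarioSpec, gen_expression, _organelle_blocks

spec = ScenarioSpec(seed=1)  # mitochondria planted at 0.75x; other lists null
matrix, truth = gen_expression(spec)
ratios = control_normalize(matrix, "WT")

results = []
for name, genes in _organelle_blocks(spec).items():
    gl = GeneList(name=name, members=frozenset(genes))
    results.append(organelle_score(ratios, gl, "WT", "KO"))
results = adjust_scores(results)

print(f"{'organelle':24s} {'n_genes':>7s} {'change':>8s} {'p_raw':>10s} {'p_adj':>10s}")
for r in results:
    print(
        f"{r.organelle:24s} {r.n_genes:7d} {percent_change(r):7.1f}% "
        f"{r.p_raw:10.2e} {r.p_adjusted:10.2e}"
    )
print(
    "\nThe planted mitochondrial repression reads out as ~-25% with a tiny "
    "adjusted p; the unplanted lists sit near 0% and are non-significant."
)
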