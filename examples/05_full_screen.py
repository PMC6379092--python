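"""The complete repressor screen, end to end, on a planted scenario.

Generates every input (expression matrix, organelle lists, promoter sets,
binding-site matrices, regulator network), writes them to disk in the
pipeline's file formats, reads them back, and runs the full screen: the
candidate list is the intersection of promoter-predicted TFs and
activity-significant TFs.
"""

import tempfile
from pathlib import Path

from mitoscreen import PipelineInputs, RunConfig, run_pipeline
from mitoscreen import io as msio
from mitoscreen.synthetic import ScenarioSpec, generate_scenario, write_scenario

sc = generate_scenario(ScenarioSpec(seed=1))

with tempfile.TemporaryDirectory() as tmp:
    paths = write_scenario(sc, Path(tmp) / "inputs")  # real file round trip
    groups = msio.read_group_map(paths["groups"])
    inputs = PipelineInputs(
        matrix=msio.read_expression_matrix(paths["expression"], groups),
        control_group="WT",
        condition_group="KO",
        organelle_lists=msio.read_gmt(paths["lists"]),
        target_promoters=msio.read_promoters_fasta(paths["target_promoters"]),
        background_promoters=msio.read_promoters_fasta(paths["background_promoters"]),
        pfms=msio.read_pfms(paths["pfms"]),
        network=msio.read_network(paths["network"]),
        name_map=msio.read_name_map(paths["name_map"]),
    )
    result = run_pipeline(RunConfig(), inputs, Path(tmp) / "out")

    print("tables written:", ", ".join(sorted(result.tables)))
    print("\ncandidate transcription factors:")
    for c in result.candidates:
        print(
            f"  {c.name} (family {c.family}): promoter coverage "
            f"{c.promoter_coverage:.2f}, family p {c.family_fisher_p:.2e}, "
            f"regulator p {c.regulator_fisher_p:.2e}, z {c.activation_z:.2f}"
        )
    print(
        "\nExactly the planted repressor survives both arms of the screen — "
        "binding sites enriched in the target promoters AND targets "
        "over-represented in the differential signature."
    )
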