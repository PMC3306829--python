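"""Run the complete pipeline on a generated planted-truth bundle.

Generates every input class with known ground truth, runs all three
prediction methods, merges them with per-edge support counts, and prints
the topology and validation summaries from the machine-readable report.
"""

import json
import tempfile
from pathlib import Path

from interolink import (
    FixtureSpec,
    RunConfig,
    plant_interaction_scenario,
    run_pipeline,
    write_bundle,
)

bundle = plant_interaction_scenario(FixtureSpec(seed=5))
print(f"bundle: {len(bundle.target)} target proteins, "
      f"{len(bundle.reference)} reference proteins, "
      f"{len(bundle.expected['merged'])} planted interactions")

with tempfile.TemporaryDirectory() as workdir:
    paths = write_bundle(bundle, Path(workdir) / "inputs")
    config = RunConfig(
        outdir=str(Path(workdir) / "out"),
        target=paths["target"],
        reference=paths["reference"],
        reference_ppis=paths["reference_ppis"],
        pssm_library=paths["pssm_library"],
        domain_annotations=paths["domain_annotations"],
        contact_records=paths["contact_records"],
        ipfam=paths["domain_pairs"],
        go=paths["go_annotations"],
        gsp=paths["gsp"],
        gsn=paths["gsn"],
        scan_threshold=1.0,
        reps_ipfam=100,
        reps_go=100,
        seed=5,
    )
    result = run_pipeline(config)
    print((Path(workdir) / "out" / "report.txt").read_text())

for method in ("interolog", "dmist", "mmist"):
    recovered = result.networks[method].edge_set() == bundle.expected[method]
    print(f"{method}: planted edges recovered exactly -> {recovered}")
# Each method recovers exactly its planted edges; the merged network carries
# per-edge support counts, and the validation block shows the planted
# domain-pair support and GO sharing standing far above the random-pair
# null (empirical p printed as 0.000 when never exceeded).
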