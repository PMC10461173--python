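"""Match a synthetic longitudinal scan pair and score it against the truth.

Generates a phantom with 20 lesions, a 12 mm smooth deformation, and a few
appearance/disappearance/split events; runs the full automated matcher with
the phantom's exact displacement field; and prints the recovered match graph
alongside the generator's ground truth.
"""

from lesionmatch import (
    MatchConfig,
    PhantomSpec,
    compare_graphs,
    generate_phantom_pair,
    match_pipeline,
    restrict_graph,
)
from lesionmatch.core import sorted_edges
from lesionmatch.registration import RegistrationConfig

spec = PhantomSpec(seed=7)
pair = generate_phantom_pair(spec)
print(f"phantom: {len(pair.labels1.labels())} lesions on scan 1, "
      f"{len(pair.labels2.labels())} on scan 2, events {pair.events}")

config = MatchConfig(registration=RegistrationConfig(mode="field"))
graph, provenance = match_pipeline(
    pair.labels1,
    pair.labels2,
    displacement_field=pair.displacement_field,
    config=config,
)
print(f"stage counts: {provenance['counts']}")
print("recovered edges (scan-1 lesion, scan-2 lesion; NEW/DISAPPEARED are "
      "sentinels):")
print(" ", sorted_edges(graph.edges))

# evaluation is limited to the lesions the matcher analysed (above 0.1 cm3)
truth = restrict_graph(pair.truth, graph.n1, graph.n2)
report = compare_graphs(graph, truth)
print(f"against ground truth: precision={report.precision:.3f} "
      f"recall={report.recall:.3f} F1={report.f1:.3f} "
      f"N_d={report.n_differences}")
print("F1=1 means every lesion correspondence, including new and "
      "disappeared lesions, was recovered exactly.")
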