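"""Full pipeline under 10-fold cross-validation on a synthetic network.

Generates a planted-structure heterogeneous network, learns embeddings
with both representation learners (adversarial + relation-typed random
walks) at 32 dimensions, concatenates them, forms Hadamard pair vectors
and evaluates a boosted-tree classifier with stratified 10-fold CV.
"""

from hetlink.pipeline import PipelineConfig, run_cv_pipeline
from hetlink.synthgen import SynthConfig, generate

data = generate(SynthConfig(seed=7))
print(
    f"synthetic network: {len(data.sm_ids)} SMs, {len(data.mirna_ids)} miRNAs, "
    f"{len(data.disease_ids)} diseases, "
    f"{len(data.associations['sm-mi'])} SM-miRNA associations"
)

report = run_cv_pipeline(data, PipelineConfig(seed=7))
print("\n10-fold CV means:")
for name, value in report.means.items():
    print(f"  {name:10s} {value:.4f}")

print(
    "\nAUC/AUPR near 1 would mean the ranking separates held-out positive\n"
    "pairs from sampled negatives almost perfectly; values in the 0.85-0.95\n"
    "range are typical for this network size and density."
)
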