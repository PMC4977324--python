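"""Simulate the study cohort.

The real 18-gene x 48-sample colorectal expression matrix is not publicly
deposited, so the analysis runs on a synthetic cohort of the same shape:
24 normal + 24 tumor samples ancestrally sampled from the published full-
network parameter tables, with Gaussian expression emission around the
binary gene states. Writes the matrix, labels and latent truth under
results/cohort/.
"""

from pathlib import Path

import wntbn as w
from wntbn.io import write_expression

OUT = Path("results/cohort")
SEED = 7

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    dataset, truth = w.generate_cohort(w.GeneratorConfig(seed=SEED))
    write_expression(dataset, OUT / "expression.tsv", OUT / "labels.csv")
    truth.states.to_json(OUT / "truth.json", orient="index")
    n_t = int((dataset.labels == 1).sum())
    print(
        f"wrote {dataset.n_genes} genes x {dataset.n_samples} samples "
        f"({n_t} tumor / {dataset.n_samples - n_t} normal), seed={SEED} -> {OUT}"
    )
    active = (dataset.matrix >= 0.5).mean(axis=1)
    print(f"fraction of measurements above the component midpoint: "
          f"min {active.min():.2f}, median {sorted(active)[len(active)//2]:.2f}, "
          f"max {active.max():.2f}")
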