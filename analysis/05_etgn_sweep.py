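"""Sweep the assumed effect of TRCMPLX on its target genes (ETGN).

ETGN (the weight 1-p applied to a gene's class-conditional activity when
the complex is on) is unidentifiable from expression data alone, so the
published protocol sweeps it over {0.5, 0.6, 0.7, 0.8, 0.9} and watches
the prediction quality. Run here on a 12+12 cohort (144 test pairs per
setting) to keep the sweep light; the sweep's shape, not its absolute
scale, is the object of interest. Writes an AUC table per variant and
setting.
"""

from pathlib import Path

import pandas as pd

import wntbn as w
from wntbn.parameters import TrainingConfig

OUT = Path("results/evaluation")
SWEEP = (0.5, 0.6, 0.7, 0.8, 0.9)

if __name__ == "__main__":
    OUT.mkdir(parents=True, exist_ok=True)
    dataset, _ = w.generate_cohort(w.GeneratorConfig(n_normal=12, n_tumor=12, seed=7))
    rows = []
    for variant in ("t1", "t2"):
        for etgn in SWEEP:
            results = w.run_ge_experiment(dataset, variant, TrainingConfig(etgn=etgn))
            labels = [r.true_label for r in results]
            rows.append(
                {
                    "variant": variant,
                    "etgn": etgn,
                    "auc_trcmplx": w.compute_roc(
                        [r.p_trcmplx for r in results], labels
                    ).auc,
                    "auc_sample": w.compute_roc(
                        [r.p_sample for r in results], labels
                    ).auc,
                }
            )
            print(f"{variant} etgn={etgn}: auc_trcmplx={rows[-1]['auc_trcmplx']:.3f} "
                  f"auc_sample={rows[-1]['auc_sample']:.3f}")
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "etgn_sweep.csv", index=False)
    print(f"\nsweep table -> {OUT / 'etgn_sweep.csv'}")
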