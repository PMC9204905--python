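#!/usr/bin/env python
"""Generate the synthetic study dataset all later analyses consume.

Builds the default study conditions: two paired tumor/normal beta cohorts
(discovery and replication), an 8 PD vs 21 CR response cohort, a ~320-sample
ten-tissue normal panel, methylation-coupled expression, paired QMSP Cq
measurements, a 200-patient plasma surveillance cohort, and a survival
table with a planted hazard ratio of 6.  Writes the bundle under
results/bundle/.
"""

import dataclasses
from pathlib import Path

import numpy as np

from methmark import io as mio
from methmark import synthetic as syn

OUT = Path(__file__).resolve().parent.parent / "results" / "bundle"
SEED = 20220617


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cohort = syn.CohortConfig(seed=SEED)
    plasma_cfg = syn.PlasmaSimConfig(seed=SEED)

    discovery = syn.simulate_beta_cohort(cohort)
    replication = syn.simulate_beta_cohort(dataclasses.replace(cohort, seed=SEED + 1))
    response = syn.simulate_response_cohort(cohort)
    panel = syn.simulate_normal_panel(cohort)
    expression = syn.simulate_expression(cohort, discovery)

    mio.write_beta_bundle(discovery, OUT, "discovery")
    mio.write_beta_bundle(replication, OUT, "replication")
    mio.write_beta_bundle(response, OUT, "response")
    mio.write_beta_bundle(panel, OUT, "normal_panel")
    expression.to_csv(OUT / "expression.tsv", sep="\t", float_format="%.6g")

    # paired QMSP measurements: half the pairs carry a 4-fold tumor elevation
    rng = np.random.default_rng([SEED, 99])
    measurements = []
    truth = []
    for i in range(1, 11):
        elevated = rng.random() < 0.5
        tumor_level = 0.05 * (4.0 if elevated else 1.0)
        truth.append((f"T{i:03d}", elevated))
        for sid, level in ((f"T{i:03d}", tumor_level), (f"N{i:03d}", 0.05)):
            measurements.append(syn.simulate_qpcr(
                level, cq_sd=0.1, seed=int(rng.integers(2**31)), sample_id=sid))
    mio.write_cq_table(measurements, OUT / "cq.csv")
    (OUT / "cq_truth.tsv").write_text(
        "sample_id\televated\n" + "\n".join(f"{s}\t{e}" for s, e in truth) + "\n")

    mio.write_plasma_table(syn.simulate_plasma_series(plasma_cfg), OUT / "plasma.csv")
    mio.write_survival_table(syn.simulate_survival(seed=SEED), OUT / "survival.csv")
    mio.write_manifest(OUT, "simulate",
                       {"cohort": dataclasses.asdict(cohort),
                        "plasma": dataclasses.asdict(plasma_cfg)}, SEED)
    print(f"wrote synthetic bundle ({cohort.n_genes} genes, "
          f"{cohort.n_pairs} pairs/cohort, {plasma_cfg.n_patients} plasma patients) "
          f"to {OUT}")


if __name__ == "__main__":
    main()
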