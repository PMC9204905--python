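#!/usr/bin/env python
"""Evaluate circulating-marker surveillance: published counts and simulation.

Part 1 reproduces the published diagnostic performance from the printed
cross-tabulations: the overall 61-patient monitored cohort (28/4 true/false
negatives among progressors, 27/2 among non-progressors) and the 36-patient
hormone-therapy subset, plus Fisher's exact tests on the two association
tables.  Part 2 runs the trajectory classifier on the simulated 200-patient
plasma cohort and benchmarks it against serum CEA and CA15-3.

Run 01_simulate_cohorts.py first (for part 2).
"""

import json
from pathlib import Path

from methmark import io as mio
from methmark.diagnostics import ConfusionTable, confusion_metrics, fisher_exact_2x2
from methmark.plasma import benchmark_markers

BUNDLE = Path(__file__).resolve().parent.parent / "results" / "bundle"
OUT = BUNDLE.parent / "surveillance"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    report = {}

    for name, table in (
        ("overall_61", ConfusionTable(tp=28, fn=4, tn=27, fp=2)),
        ("hormone_36", ConfusionTable(tp=10, fn=3, tn=22, fp=1)),
    ):
        pct = confusion_metrics(table).percent(1)
        report[name] = pct
        print(f"{name}: sensitivity {pct['sensitivity']}%  "
              f"specificity {pct['specificity']}%  accuracy {pct['accuracy']}%")

    for name, tab in (
        ("tumor_methylation_vs_hormone_response", [[21, 3], [2, 9]]),
        ("plasma_methylation_vs_progression", [[27, 4], [2, 28]]),
    ):
        p, odds = fisher_exact_2x2(tab)
        report[name] = {"fisher_p": p, "odds_ratio": odds}
        print(f"{name}: Fisher p = {p:.3g}, OR = {odds:.1f}")

    cohort = mio.read_plasma_table(BUNDLE / "plasma.csv")
    bench = benchmark_markers(cohort)
    sim = {}
    for marker, res in bench.items():
        pct = res["report"].percent(1)
        sim[marker] = {**pct, "auc": round(res["roc"].auc, 4)}
        print(f"simulated {marker}: sensitivity {pct['sensitivity']}%  "
              f"specificity {pct['specificity']}%  AUC {res['roc'].auc:.3f}")
    report["simulated_cohort"] = sim

    (OUT / "surveillance_report.json").write_text(json.dumps(report, indent=2) + "\n")
    print(f"wrote {OUT / 'surveillance_report.json'}")


if __name__ == "__main__":
    main()
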