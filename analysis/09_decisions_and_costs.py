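"""Check-based advancement decisions and the cost-benefit scenario.

Uses the APP GEBVs from 07: the first check line (simulated benchmark
cultivar) sets the observed- and predicted-space thresholds; candidates
advancing under genomic pre-selection are compared with the observed
winners, and the realized reduction feeds the cost model for a 300-line
program at 6 M reads/sample.  Writes results/decision_report.json and
results/cost_scenario.json.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

import _shared
from flaxgs import decide, economics


def main():
    _shared.ensure_dirs()
    src = _shared.SCRATCH / "app_gebvs.csv"
    if not src.exists():
        sys.exit("run 07_across_population_prediction.py first")
    gebvs = pd.read_csv(src)

    reports = {}
    for popname, sub in gebvs.groupby("population"):
        # benchmark check: the median-observed line, mimicking a released
        # cultivar of typical performance grown alongside the candidates
        order = sub.sort_values("observed")
        benchmark = order.iloc[len(order) // 2]["line"]
        spec = decide.CheckSpec(check_ids=(benchmark,), benchmark=benchmark)
        observed = sub.set_index("line")["observed"]
        predicted = sub.set_index("line")["gebv"]
        report = decide.check_based_selection(observed, predicted, spec)
        reports[popname] = report.to_dict()
        ret = report.retention_percent
        print(
            f"{popname}: {report.n_total} candidates, "
            f"{len(report.advanced)} advanced "
            f"({report.reduction_percent}% reduction), retention "
            f"{'n/a' if ret is None else f'{ret}%'}"
        )

    (_shared.RESULTS / "decision_report.json").write_text(
        json.dumps(reports, indent=2, default=str) + "\n"
    )

    reductions = [r["reduction_percent"] for r in reports.values()]
    sc = economics.scenario(300, 6, (min(reductions), max(reductions)))
    (_shared.RESULTS / "cost_scenario.json").write_text(
        json.dumps(sc.to_dict(), indent=2) + "\n"
    )
    print(
        f"\n300-line program: conventional ${sc.conventional_total:,.0f}, "
        f"GS-assisted ${sc.gs_totals[0]:,.0f}-${sc.gs_totals[1]:,.0f} "
        f"({sc.savings_percent[1]}-{sc.savings_percent[0]}% savings)"
    )


if __name__ == "__main__":
    main()
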