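"""Expression-based survival stratification on a synthetic cohort.

Applies the five fixed grouping rules (median, average, first/last
quartile, first-vs-last quartile) and the scan-method cutpoint to a
simulated cohort in which higher expression raises the hazard, then
repeats the scan on a null cohort to show the multiplicity effect of
maximizing the log-rank statistic over cutoffs.
"""

import json
import sys
from pathlib import Path

ROOT = Path(__file__).resolve().parents[1]
sys.path.insert(0, str(ROOT / "src"))

from screenhit.survival import (
    log_rank_test,
    scan_cutpoint,
    simulate_survival_cohort,
    split_by_expression,
)

RESULTS = ROOT / "results"
FIXED_METHODS = (
    "median", "average", "first_quartile", "last_quartile", "first_vs_last_quartile",
)


def analyze(df):
    t = df.time.to_numpy()
    e = df.event.to_numpy()
    x = df.expression.to_numpy()
    out = {}
    for method in FIXED_METHODS:
        labels = split_by_expression(x, method)
        low, high = labels == "low", labels == "high"
        res = log_rank_test(t[low], e[low], t[high], e[high])
        out[method] = {
            "n_low": int(low.sum()),
            "n_high": int(high.sum()),
            "statistic": round(res.statistic, 4),
            "p": float(f"{res.p:.3e}"),
        }
    scan = scan_cutpoint(t, e, x)
    out["scan"] = {
        "best_cutoff": round(scan.best_cutoff, 4),
        "statistic": round(scan.best_statistic, 4),
        "p": float(f"{scan.best_p:.3e}"),
        "n_scanned": scan.n_scanned,
        "note": "nominal p, uncorrected for scanning multiplicity",
    }
    return out, scan


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    cohort = simulate_survival_cohort(120, effect=0.6, seed=42)
    effect_results, scan = analyze(cohort)
    null_cohort = simulate_survival_cohort(120, effect=0.0, seed=43)
    null_results, _ = analyze(null_cohort)

    report = {
        "cohort_with_effect": effect_results,
        "null_cohort": null_results,
    }
    scan.to_frame().to_csv(RESULTS / "04_scan_table.tsv", sep="\t", index=False)
    (RESULTS / "04_survival.json").write_text(json.dumps(report, indent=2))
    print(json.dumps(report, indent=2))
    print(
        "\nNote how the scan method's best p undercuts the fixed rules even "
        "on the null cohort: the maximum over "
        f"{null_results['scan']['n_scanned']} cutoffs is anti-conservative."
    )


if __name__ == "__main__":
    main()
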