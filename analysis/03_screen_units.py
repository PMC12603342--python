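"""Screen units for stimulus responsiveness and odor association.

Reads the session written by 02_simulate_session.py, computes window
firing rates and baseline z-scores for first-presentation trials, applies
the 2 Hz inclusion filter, runs the Bonferroni-corrected per-unit t-test
families, and tests per-region prevalence against chance with exact
binomial tests.  Writes the per-unit tables and the two region summaries.
"""

import pandas as pd

from pathlib import Path

from odorwords import io, population, rates, screening

BASE = Path(__file__).resolve().parent.parent / "results"
SESSION = BASE / "session"


def main() -> None:
    spikes = io.read_spikes(SESSION / "spikes.csv")
    trials = io.read_trials(SESSION / "trials.csv")
    tensor = rates.build_rate_tensor(spikes, trials)
    retained = rates.apply_rate_filter(tensor)
    print(
        f"{int(retained.sum())} of {tensor.n_units} units pass the 2 Hz filter "
        f"({int((~retained).sum())} dropped)"
    )
    tensor = rates.zscore_rates(tensor.select_units(retained))
    totals = pd.Series(tensor.regions).value_counts().to_dict()

    for mode, title in [
        ("stimulus", "Units responsive to object words"),
        ("odor", "Units with odor-related vs control differences"),
    ]:
        results = screening.screen_units(tensor, mode)
        summary = population.summarize_screening(results, totals)
        results.to_csv(BASE / f"screening_{mode}.csv", index=False)
        summary.to_csv(BASE / f"summary_{mode}.csv", index=False)
        print()
        print(population.render_summary_table(summary, title))

    # recovery against ground truth, where available
    gt_path = SESSION / "ground_truth.csv"
    if gt_path.exists():
        gt = pd.read_csv(gt_path)
        odor_results = pd.read_csv(BASE / "screening_odor.csv")
        truth = set(gt[gt["is_odor_associated"]]["unit_id"])
        flagged = set(odor_results[odor_results["flagged"]]["unit_id"])
        retained_truth = truth & set(odor_results["unit_id"])
        if retained_truth:
            rec = len(retained_truth & flagged) / len(retained_truth)
            print(
                f"ground-truth check: {len(retained_truth & flagged)} of "
                f"{len(retained_truth)} retained odor-associated units recovered "
                f"({100 * rec:.0f}%)"
            )


if __name__ == "__main__":
    main()
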