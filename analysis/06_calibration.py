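"""Null calibration of the three inferential stages.

Under null synthetic data (no condition-dependent rates), measures the
family-wise flag rate of the per-unit screening, the rejection rate of
the CATEGORY x REGION ensemble interaction, and the false-positive rate
of the ensemble cluster permutation test.  All three should sit near the
nominal 5%.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from odorwords import cluster, ensemble, rates, screening, stimuli, synthetic

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-sims", type=int, default=500)
    args = parser.parse_args()
    rng = np.random.default_rng(args.seed)
    seq = stimuli.make_trial_sequence(stimuli.default_word_list(), 100, 100, seed=rng)
    trials = seq[seq["presentation"] == 1].reset_index(drop=True)
    ws = rates.WindowSet()
    rows = []

    counts = synthetic.poisson_window_counts(
        np.full((1000, 200, 5), 4.0), ws.durations_s, rng
    )
    tensor = rates.zscore_rates(
        rates.tensor_from_counts(counts, np.full(1000, "amygdala"), trials, ws)
    )
    rate = float(screening.screen_units(tensor, "stimulus")["flagged"].mean())
    rows.append(("screening_familywise_flag_rate", rate, 1000))
    print(f"screening family-wise flag rate: {rate:.3f} (1000 null units)")

    regions = np.concatenate(
        [np.repeat(r, n) for r, n in synthetic.DEFAULT_UNITS_PER_REGION.items()]
    )
    rej = 0
    for _ in range(args.n_sims):
        counts = synthetic.poisson_window_counts(
            np.full((195, 200, 5), 4.0), ws.durations_s, rng
        )
        t = rates.zscore_rates(rates.tensor_from_counts(counts, regions, trials, ws))
        table = ensemble.mixed_anova(ensemble.build_cell_means(t, "ODOR")).set_index(
            "effect"
        )
        rej += table.loc["ODOR x REGION", "p"] < 0.05
    rows.append(("anova_interaction_rejection_rate", rej / args.n_sims, args.n_sims))
    print(f"ANOVA ODOR x REGION rejection rate: {rej / args.n_sims:.3f}")

    hits = 0
    for _ in range(args.n_sims):
        a, b = synthetic.null_ensemble_rate_series(57, 100, 4.0, 220, 0.01, rng)
        res = cluster.cluster_permutation_test(
            cluster.smooth_counts(a, 0.01, 0.05),
            cluster.smooth_counts(b, 0.01, 0.05),
            paired=True,
            n_perm=1000,
            seed=rng,
        )
        hits += any(c.p < 0.05 for c in res.clusters)
    rows.append(("cluster_false_positive_rate", hits / args.n_sims, args.n_sims))
    print(f"cluster test false-positive rate: {hits / args.n_sims:.3f}")

    BASE.mkdir(exist_ok=True)
    pd.DataFrame(rows, columns=["quantity", "value", "n"]).to_csv(
        BASE / "calibration.csv", index=False
    )
    print(f"wrote {BASE / 'calibration.csv'}")


if __name__ == "__main__":
    main()
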