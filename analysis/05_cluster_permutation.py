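"""Cluster-based permutation tests on time-resolved firing rates.

Runs the ensemble odor-versus-control cluster test over amygdala units
(paired sign-flip permutations of the per-unit difference series) and,
for the strongest flagged odor-associated unit, the per-unit
odor-versus-control test (trial-label shuffles).
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from odorwords import cluster, io, rates

BASE = Path(__file__).resolve().parent.parent / "results"
SESSION = BASE / "session"


def describe(result, label: str) -> None:
    print(f"{label} ({result.n_permutations} permutations):")
    if not result.clusters:
        print("  no supra-threshold clusters")
    for c in result.clusters:
        tag = "cluster-level significant" if c.p < 0.05 else "alpha-threshold only"
        print(
            f"  [{1000 * c.start_s:.0f}, {1000 * c.end_s:.0f}] ms  "
            f"mass {c.mass:.2f}  p = {c.p:.4f}  ({tag})"
        )


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--n-perm", type=int, default=10000)
    args = parser.parse_args()

    spikes = io.read_spikes(SESSION / "spikes.csv")
    trials = io.read_trials(SESSION / "trials.csv")
    tensor = rates.build_rate_tensor(spikes, trials)
    tensor = rates.zscore_rates(tensor.select_units(rates.apply_rate_filter(tensor)))

    res = cluster.ensemble_odor_cluster_test(
        spikes, tensor, region="amygdala", n_perm=args.n_perm, seed=args.seed
    )
    frame = res.to_frame()
    if frame.empty:
        frame = pd.DataFrame(columns=["start_s", "end_s", "mass", "p"])
    frame.to_csv(BASE / "clusters_ensemble_amygdala.csv", index=False)
    describe(res, "ensemble odor vs control, amygdala")

    screen_path = BASE / "screening_odor.csv"
    if screen_path.exists():
        odor = pd.read_csv(screen_path)
        flagged = odor[odor["flagged"]]
        if len(flagged):
            best = flagged.loc[flagged[["p1", "p2", "p3", "p4"]].min(axis=1).idxmin()]
            res_u = cluster.unit_odor_cluster_test(
                spikes, trials, str(best["unit_id"]), n_perm=args.n_perm, seed=args.seed
            )
            res_u.to_frame().to_csv(BASE / "clusters_best_unit.csv", index=False)
            describe(res_u, f"unit {best['unit_id']} odor vs control")


if __name__ == "__main__":
    main()
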