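"""Simulate the reference recording session with known ground truth.

One continuous-recognition run: 300 word trials (100 once, 100 twice,
0.5 s display, 1.7-2.3 s jitter) recorded by 195 synthetic units across
five mediotemporal regions, with per-region fractions of
stimulus-responsive and odor-associated units matching the observed
prevalences.  Writes spikes, trials and the generative ground truth.
"""

import argparse
from pathlib import Path

from odorwords import io, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "session"


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    session = synthetic.simulate_session(synthetic.SyntheticConfig(seed=args.seed))
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_spikes(session.spikes, OUT / "spikes.csv")
    io.write_trials(session.trials, OUT / "trials.csv")
    session.ground_truth.to_csv(OUT / "ground_truth.csv", index=False)

    gt = session.ground_truth
    n_spikes = sum(len(t) for t in session.spikes.trains.values())
    print(f"simulated session (seed {args.seed}):")
    print(f"  units: {len(session.spikes)} across {gt['region'].nunique()} regions")
    print(f"  trials: {len(session.trials)}, total spikes: {n_spikes}")
    print(
        f"  ground truth: {int(gt['is_responsive'].sum())} responsive, "
        f"{int(gt['is_odor_associated'].sum())} odor-associated"
    )
    print(f"wrote session files to {OUT}")


if __name__ == "__main__":
    main()
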