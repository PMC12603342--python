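"""Shared test utilities (imported by test modules, not a fixture file)."""

import numpy as np

from odorwords import rates, synthetic


def make_null_tensor(
    n_units: int,
    trials,
    rate_hz: float = 4.0,
    seed: int = 0,
    regions=None,
) -> rates.RateTensor:
    """Null tensor: every unit fires at a constant rate in every window."""
    rng = np.random.default_rng(seed)
    windows = rates.WindowSet()
    lam = np.full((n_units, len(trials), windows.n_windows), rate_hz)
    counts = synthetic.poisson_window_counts(lam, windows.durations_s, rng)
    if regions is None:
        regions = np.full(n_units, "amygdala")
    return rates.tensor_from_counts(counts, regions, trials, windows)
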