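"""Per-unit screening for stimulus-responsive and odor-associated neurons.

Stimulus responsiveness: four two-sided paired t-tests (each post window's
z-scored rate against the baseline window, paired across first-presentation
trials); a unit is flagged when at least one test beats the
Bonferroni-corrected threshold alpha/4 = 0.0125.  Odor association: four
two-sided unpaired t-tests (odor-word versus control-word trials within
each post window) under the same family correction.  Benjamini-Hochberg
step-up control over the same four-test family is available as the less
conservative alternative.  Both contrasts can equivalently be run on raw
rates: the paired contrast is invariant to the per-unit affine z-transform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from odorwords.rates import RateTensor

__all__ = [
    "UnitTestResult",
    "test_stimulus_responsiveness",
    "test_odor_association",
    "benjamini_hochberg",
    "screen_units",
]

log = logging.getLogger(__name__)

SCREENING_COLUMNS = [
    "unit_id",
    "region",
    "p1",
    "p2",
    "p3",
    "p4",
    "t1",
    "t2",
    "t3",
    "t4",
    "flagged",
    "best_window",
    "direction",
    "correction_method",
]


@dataclass
class UnitTestResult:
    """Outcome of one unit's four-window screening family."""

    unit_id: str
    region: str
    p: np.ndarray  # (4,) per post window
    t: np.ndarray  # (4,)
    flagged: bool
    best_window: int | None  # 0-based post-window index of the smallest p
    direction: str | None  # 'increase' | 'decrease', defined only when flagged
    correction_method: str = "bonferroni"

    def to_row(self) -> list:
        return [
            self.unit_id,
            self.region,
            *map(float, self.p),
            *map(float, self.t),
            bool(self.flagged),
            None if self.best_window is None else int(self.best_window),
            self.direction,
            self.correction_method,
        ]


def _family_flags(p: np.ndarray, alpha_family: float, correction: str) -> np.ndarray:
    if correction == "bonferroni":
        return p < alpha_family / len(p)
    if correction == "bh":
        return benjamini_hochberg(p, q=alpha_family)
    raise ValueError(f"unknown correction {correction!r}")


def _finalize(
    unit_id: str,
    region: str,
    t: np.ndarray,
    p: np.ndarray,
    contrast_means: np.ndarray,
    alpha_family: float,
    correction: str,
) -> UnitTestResult:
    rejected = _family_flags(p, alpha_family, correction)
    flagged = bool(rejected.any())
    best = int(np.argmin(p)) if flagged else None
    direction = None
    if flagged:
        direction = "increase" if contrast_means[best] > 0 else "decrease"
        signs = np.sign(contrast_means[rejected])
        if len(set(signs.tolist())) > 1:
            log.info(
                "unit %s: significant windows have mixed directions; "
                "direction taken from the smallest-p window",
                unit_id,
            )
    return UnitTestResult(
        unit_id, region, p, t, flagged, best, direction, correction
    )


def test_stimulus_responsiveness(
    values: np.ndarray,
    unit_id: str = "",
    region: str = "",
    alpha_family: float = 0.05,
    correction: str = "bonferroni",
) -> UnitTestResult:
    """Paired post-versus-baseline t-tests for one unit.

    ``values`` is a (trials, 5) array of z-scored (or raw) rates with the
    baseline window in column 0 followed by the four post windows.  Windows
    with zero variance of the paired differences get p = 1 (guard).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2 or values.shape[1] < 2:
        raise ValueError("values must be (trials, baseline + post windows)")
    if values.shape[0] < 2:
        raise ValueError("need at least 2 trials")
    baseline = values[:, 0]
    n_post = values.shape[1] - 1
    t = np.zeros(n_post)
    p = np.ones(n_post)
    deltas = np.empty(n_post)
    for w in range(n_post):
        diff = values[:, w + 1] - baseline
        deltas[w] = diff.mean()
        if np.std(diff, ddof=1) == 0.0:
            t[w], p[w] = 0.0, 1.0  # zero-variance guard
            continue
        res = stats.ttest_rel(values[:, w + 1], baseline)
        t[w], p[w] = float(res.statistic), float(res.pvalue)
    return _finalize(unit_id, region, t, p, deltas, alpha_family, correction)


def test_odor_association(
    post_values: np.ndarray,
    condition: np.ndarray,
    unit_id: str = "",
    region: str = "",
    alpha_family: float = 0.05,
    correction: str = "bonferroni",
    welch: bool = False,
) -> UnitTestResult:
    """Unpaired odor-versus-control t-tests within each post window.

    ``post_values`` is (trials, 4) and ``condition`` a boolean per-trial
    mask (True = odor-word trial).  Direction is the sign of (mean odor -
    mean control) in the most significant window.  Windows where both
    groups have zero variance get p = 1 when the means are equal.
    """
    post_values = np.asarray(post_values, dtype=float)
    condition = np.asarray(condition, dtype=bool)
    if post_values.shape[0] != condition.shape[0]:
        raise ValueError("condition mask must have one entry per trial")
    a = post_values[condition]
    b = post_values[~condition]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both conditions need at least 2 trials")
    n_post = post_values.shape[1]
    t = np.zeros(n_post)
    p = np.ones(n_post)
    deltas = a.mean(axis=0) - b.mean(axis=0)
    for w in range(n_post):
        if np.std(a[:, w], ddof=1) == 0.0 and np.std(b[:, w], ddof=1) == 0.0:
            if deltas[w] == 0.0:
                t[w], p[w] = 0.0, 1.0  # zero-variance guard
            else:
                t[w] = np.inf if deltas[w] > 0 else -np.inf
                p[w] = 0.0
            continue
        res = stats.ttest_ind(a[:, w], b[:, w], equal_var=not welch)
        t[w], p[w] = float(res.statistic), float(res.pvalue)
    return _finalize(unit_id, region, t, p, deltas, alpha_family, correction)


def benjamini_hochberg(p_values, q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up rejection flags at FDR level ``q``.

    Rejections are always a superset of Bonferroni rejections at the same
    family level.  An empty input yields an empty flag array.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def screen_units(
    tensor: RateTensor,
    mode: str = "stimulus",
    alpha_family: float = 0.05,
    correction: str = "bonferroni",
    use_z: bool = True,
) -> pd.DataFrame:
    """Screen every z-eligible unit in a tensor; returns one row per unit.

    ``mode`` is ``'stimulus'`` (paired post-vs-baseline) or ``'odor'``
    (unpaired odor-vs-control).  Units excluded from z-scoring (zero
    baseline SD) are skipped when ``use_z`` is set.
    """
    if use_z and tensor.z is None:
        raise ValueError("tensor has no z-scores; run zscore_rates first")
    values = tensor.z if use_z else tensor.rates
    condition = tensor.is_odor
    rows = []
    for i, uid in enumerate(tensor.unit_ids):
        uid = str(uid)
        if use_z and uid in tensor.zscore_excluded:
            continue
        v = values[i]
        if mode == "stimulus":
            res = test_stimulus_responsiveness(
                v, uid, str(tensor.regions[i]), alpha_family, correction
            )
        elif mode == "odor":
            res = test_odor_association(
                v[:, 1:], condition, uid, str(tensor.regions[i]), alpha_family, correction
            )
        else:
            raise ValueError(f"unknown screening mode {mode!r}")
        rows.append(res.to_row())
    return pd.DataFrame(rows, columns=SCREENING_COLUMNS)
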