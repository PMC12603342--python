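"""Ensemble statistics: split-plot mixed ANOVA of z-scored window rates.

Units are the random observations.  Each unit contributes a complete
2 x T cell-mean matrix (CATEGORY level x TIME window, averaged over its
first-presentation trials); REGION is the between-unit factor.  The
univariate split-plot decomposition tests the between-unit stratum
(REGION against units-within-region) and, in each within-unit stratum
built from orthonormal contrasts, the within effect and its interaction
with REGION against the corresponding effect-by-units-within-region error
term.  Unbalanced region sizes are handled Type III style: within main
effects test the unweighted mean of region means.  No sphericity
correction is applied (the reference analysis reports uncorrected df).

The category scheme is ODOR (odor-related vs control words), LIVING, or
FOOD; post hoc LSD tests compare the unit-level category marginals within
each region without multiplicity correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from odorwords.rates import RateTensor
from odorwords.synthetic import REGIONS

__all__ = [
    "CellMeansTable",
    "AnovaResult",
    "PosthocResult",
    "build_cell_means",
    "mixed_anova",
    "lsd_posthoc",
    "food_within_odor_anova",
]

log = logging.getLogger(__name__)

ANOVA_COLUMNS = ["effect", "F", "df_num", "df_den", "p", "partial_eta_sq"]


@dataclass
class CellMeansTable:
    """Per-unit 2 x T cell means for one category scheme.

    ``data[n, 0, :]`` holds unit n's means for the in-category level
    (odor / living / food), ``data[n, 1, :]`` the complement, across the T
    post-stimulus windows.
    """

    unit_ids: np.ndarray
    regions: np.ndarray
    data: np.ndarray  # (N, 2, T)
    scheme: str
    excluded: dict[str, str] = field(default_factory=dict)

    @property
    def n_units(self) -> int:
        return len(self.unit_ids)

    @property
    def n_time(self) -> int:
        return self.data.shape[2]


@dataclass(frozen=True)
class AnovaResult:
    effect: str
    F: float
    df_num: int
    df_den: int
    p: float
    partial_eta_sq: float


@dataclass(frozen=True)
class PosthocResult:
    """LSD comparison of category marginals within one region."""

    region: str
    scheme: str
    n_units: int
    mean_in: float
    sem_in: float
    mean_out: float
    sem_out: float
    p: float
    cohen_d: float


def build_cell_means(
    tensor: RateTensor, scheme: str = "ODOR", use_z: bool = True
) -> CellMeansTable:
    """Across-trial cell means per unit for a 2 x T CATEGORY x TIME design.

    T is the number of post windows in the tensor (4 at 500 ms resolution,
    20 at 100 ms).  Units with no trials in a category level, or excluded
    from z-scoring, are dropped and logged; an empty result raises.
    """
    values = tensor.z if use_z else tensor.rates
    if use_z and values is None:
        raise ValueError("tensor has no z-scores; run zscore_rates first")
    mask_in = tensor.condition_mask(scheme)
    if mask_in.all() or not mask_in.any():
        raise ValueError(f"scheme {scheme}: all trials fall in a single level")
    keep, rows, excluded = [], [], {}
    for i, uid in enumerate(tensor.unit_ids):
        uid = str(uid)
        if use_z and uid in tensor.zscore_excluded:
            excluded[uid] = tensor.zscore_excluded[uid]
            continue
        cell_in = values[i][mask_in, 1:].mean(axis=0)
        cell_out = values[i][~mask_in, 1:].mean(axis=0)
        keep.append(i)
        rows.append(np.stack([cell_in, cell_out]))
    if not rows:
        raise ValueError("no unit has complete category cells")
    for uid, reason in excluded.items():
        log.info("cell means: unit %s excluded (%s)", uid, reason)
    keep = np.asarray(keep)
    return CellMeansTable(
        unit_ids=tensor.unit_ids[keep],
        regions=tensor.regions[keep],
        data=np.stack(rows),
        scheme=scheme.upper(),
        excluded=excluded,
    )


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """(k, k-1) Helmert-style contrasts, columns orthonormal and summing to 0."""
    c = np.zeros((k, k - 1))
    for j in range(1, k):
        c[:j, j - 1] = 1.0
        c[j, j - 1] = -j
    return c / np.linalg.norm(c, axis=0)


def _stratum_f(
    scores: np.ndarray, group_idx: list[np.ndarray]
) -> tuple[tuple[float, float, int], tuple[float, float, int] | None, float, int]:
    """Hypothesis and error quantities of one within-unit stratum.

    Returns ((SS_main, df), (SS_interaction, df) or None, SS_error, df_error)
    for orthonormal-contrast ``scores`` (N x q) grouped into regions.
    Main effects use the Type III (unweighted region mean) hypothesis.
    """
    q = scores.shape[1]
    a = len(group_idx)
    n_i = np.array([len(g) for g in group_idx])
    means = np.stack([scores[g].mean(axis=0) for g in group_idx])  # (a, q)
    ss_err = sum(
        float(((scores[g] - means[i]) ** 2).sum()) for i, g in enumerate(group_idx)
    )
    df_err = q * int(n_i.sum() - a)
    ghat = means.mean(axis=0)
    c = (1.0 / a**2) * float((1.0 / n_i).sum())
    ss_main = float((ghat**2).sum() / c)
    main = (ss_main, q)
    if a > 1:
        wbar = (n_i[:, None] * means).sum(axis=0) / n_i.sum()
        ss_int = float((n_i[:, None] * (means - wbar) ** 2).sum())
        inter = (ss_int, q * (a - 1))
    else:
        inter = None
    return main, inter, ss_err, df_err


def _f_row(
    effect: str,
    ss: float,
    df_num: int,
    ss_err: float,
    df_err: int,
    eps: float = 1.0,
    scale: float = 0.0,
) -> AnovaResult:
    # sums of squares negligible relative to the data scale are exact zeros
    tol = 1e-12 * scale
    if ss <= tol:
        ss = 0.0
    if ss_err <= tol:
        ss_err = 0.0
    if ss_err <= 0.0:
        if ss <= 0.0:
            return AnovaResult(effect, 0.0, df_num, df_err, 1.0, 0.0)
        return AnovaResult(effect, np.inf, df_num, df_err, 0.0, 1.0)
    F = (ss / df_num) / (ss_err / df_err)
    p = float(stats.f.sf(F, eps * df_num, eps * df_err))
    eta = ss / (ss + ss_err)
    return AnovaResult(effect, float(F), df_num, df_err, p, float(eta))


def mixed_anova(
    cells: CellMeansTable, sphericity_correction: str | None = None
) -> pd.DataFrame:
    """Split-plot ANOVA: within factors CATEGORY x TIME, between factor REGION.

    Returns one row per effect (REGION; CATEGORY, CATEGORY x REGION; TIME,
    TIME x REGION; CATEGORY x TIME, CATEGORY x TIME x REGION) with F,
    degrees of freedom, p, and partial eta squared
    (= F df_num / (F df_num + df_den)).  With a single region present the
    between factor and its interactions are omitted (pure repeated
    measures).  ``sphericity_correction='gg'`` applies Greenhouse-Geisser
    epsilon to the df of multi-contrast within strata (p changes; F does
    not).  Raises for a region with fewer than 2 units.
    """
    Y = cells.data
    N, _, T = Y.shape
    present = [r for r in REGIONS if r in set(cells.regions)]
    present += sorted(set(cells.regions) - set(REGIONS))
    group_idx = [np.flatnonzero(cells.regions == r) for r in present]
    for r, g in zip(present, group_idx):
        if len(g) < 2:
            raise ValueError(f"region {r!r} has fewer than 2 units")
    a = len(present)
    flat = Y.reshape(N, 2 * T)
    cat = cells.scheme

    data_scale = float(((flat - flat.mean()) ** 2).sum()) if N else 0.0

    # between-unit stratum: unit means (scaled to keep SS on the cell scale)
    u = flat.mean(axis=1) * np.sqrt(2 * T)
    rows: list[AnovaResult] = []
    if a > 1:
        n_i = np.array([len(g) for g in group_idx])
        m_i = np.array([u[g].mean() for g in group_idx])
        grand = float((n_i * m_i).sum() / n_i.sum())
        ss_region = float((n_i * (m_i - grand) ** 2).sum())
        ss_err_b = sum(float(((u[g] - m_i[i]) ** 2).sum()) for i, g in enumerate(group_idx))
        rows.append(
            _f_row("REGION", ss_region, a - 1, ss_err_b, N - a, scale=data_scale)
        )

    # within-unit strata via orthonormal contrasts of the 2 x T cell space
    cc = _orthonormal_contrasts(2)  # (2, 1)
    ct = _orthonormal_contrasts(T)  # (T, T-1)
    ones_t = np.full((T, 1), 1.0 / np.sqrt(T))
    ones_c = np.full((2, 1), 1.0 / np.sqrt(2))
    strata = [
        (cat, np.kron(cc, ones_t)),
        ("TIME", np.kron(ones_c, ct)),
        (f"{cat} x TIME", np.kron(cc, ct)),
    ]
    for name, C in strata:
        if C.shape[1] == 0:  # degenerate single-level factor
            continue
        scores = flat @ C
        eps = 1.0
        if sphericity_correction == "gg" and scores.shape[1] > 1:
            eps = _gg_epsilon(scores, group_idx)
        elif sphericity_correction not in (None, "gg"):
            raise ValueError(f"unknown sphericity correction {sphericity_correction!r}")
        (ss_main, df_main), inter, ss_err, df_err = _stratum_f(scores, group_idx)
        rows.append(_f_row(name, ss_main, df_main, ss_err, df_err, eps, data_scale))
        if inter is not None:
            ss_int, df_int = inter
            rows.append(
                _f_row(f"{name} x REGION", ss_int, df_int, ss_err, df_err, eps, data_scale)
            )
    return pd.DataFrame([vars(r) for r in rows], columns=ANOVA_COLUMNS)


def _gg_epsilon(scores: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """Greenhouse-Geisser epsilon from the pooled within-group covariance."""
    q = scores.shape[1]
    pooled = np.zeros((q, q))
    df = 0
    for g in group_idx:
        if len(g) < 2:
            continue
        resid = scores[g] - scores[g].mean(axis=0)
        pooled += resid.T @ resid
        df += len(g) - 1
    pooled /= max(df, 1)
    tr = np.trace(pooled)
    denom = q * float((pooled * pooled.T).sum())
    if denom <= 0.0:
        return 1.0
    return float(np.clip(tr**2 / denom, 1.0 / q, 1.0))


def lsd_posthoc(
    cells: CellMeansTable,
    region: str | None = None,
    pooled_error: bool = False,
) -> pd.DataFrame:
    """Fisher LSD comparisons of category marginals, one row per region.

    The observation for each unit is its time-averaged cell mean per
    category level.  Default: an uncorrected paired t-test of the
    difference within each region, with Cohen's d = mean difference / SD
    of the unit-level differences.  ``pooled_error=True`` uses the classic
    LSD error term: the difference variance pooled across regions with
    df = N - n_regions.
    """
    marg_in = cells.data[:, 0, :].mean(axis=1)
    marg_out = cells.data[:, 1, :].mean(axis=1)
    diff = marg_in - marg_out
    present = [r for r in REGIONS if r in set(cells.regions)]
    present += sorted(set(cells.regions) - set(REGIONS))
    if region is not None:
        if region not in present:
            raise ValueError(f"region {region!r} not present")
        present = [region]
    group_idx = {r: np.flatnonzero(cells.regions == r) for r in present}
    for r, g in group_idx.items():
        if len(g) < 2:
            raise ValueError(f"region {r!r} has fewer than 2 units")
    if pooled_error:
        all_groups = [np.flatnonzero(cells.regions == r) for r in set(cells.regions)]
        ss = sum(float(((diff[g] - diff[g].mean()) ** 2).sum()) for g in all_groups)
        df_pool = len(diff) - len(all_groups)
        ms_pool = ss / df_pool if df_pool > 0 else 0.0
    rows = []
    for r in present:
        g = group_idx[r]
        d = diff[g]
        n = len(g)
        sd = float(np.std(d, ddof=1))
        dbar = float(d.mean())
        if pooled_error:
            se = np.sqrt(ms_pool / n)
            df = df_pool
        else:
            se = sd / np.sqrt(n)
            df = n - 1
        if se == 0.0:
            if dbar == 0.0:
                t, p = 0.0, 1.0
            else:
                warnings.warn(
                    f"region {r}: zero-variance differences with nonzero mean",
                    RuntimeWarning,
                    stacklevel=2,
                )
                t, p = np.sign(dbar) * np.inf, 0.0
        else:
            t = dbar / se
            p = float(2.0 * stats.t.sf(abs(t), df))
        cohen_d = 0.0 if sd == 0.0 else dbar / sd
        rows.append(
            PosthocResult(
                region=r,
                scheme=cells.scheme,
                n_units=n,
                mean_in=float(marg_in[g].mean()),
                sem_in=float(np.std(marg_in[g], ddof=1) / np.sqrt(n)),
                mean_out=float(marg_out[g].mean()),
                sem_out=float(np.std(marg_out[g], ddof=1) / np.sqrt(n)),
                p=p,
                cohen_d=float(cohen_d),
            )
        )
    return pd.DataFrame([vars(r) for r in rows])


def food_within_odor_anova(
    tensor: RateTensor, region: str = "amygdala", use_z: bool = True
) -> pd.DataFrame:
    """Two-within-factor RM ANOVA (FOOD x TIME) on odor-word trials of one region.

    Restricts trials to odor-related words, splits them food versus
    nonfood, restricts units to ``region``, and runs the repeated-measures
    decomposition; the FOOD main effect has df = (1, N - 1).
    """
    odor_trials = tensor.is_odor
    sub = tensor.select_units(tensor.regions == region)
    if sub.n_units == 0:
        raise ValueError(f"region {region!r} has no units")
    from dataclasses import replace as _replace

    sub = _replace(
        sub,
        trials=sub.trials[odor_trials].reset_index(drop=True),
        counts=sub.counts[:, odor_trials, :],
        z=None if sub.z is None else sub.z[:, odor_trials, :],
    )
    cells = build_cell_means(sub, scheme="FOOD", use_z=use_z)
    return mixed_anova(cells)
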