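"""Region-level prevalence tests for flagged units.

Whether the number of flagged units in a region exceeds what per-unit
screening at alpha = 0.05 would produce by chance is assessed with an
exact one-sided upper-tail binomial test: p = P(X >= k) for
X ~ Binomial(n, 0.05), computed by exact tail summation, never a normal
approximation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from odorwords.synthetic import REGIONS

__all__ = [
    "BinomialResult",
    "binomial_prevalence_test",
    "summarize_screening",
    "format_p",
    "render_summary_table",
]

REGION_TITLES = {
    "amygdala": "Amygdala",
    "hippocampus": "Hippocampus",
    "entorhinal": "Entorhinal cortex",
    "parahippocampal": "Parahippocampal cortex",
    "piriform": "Piriform cortex",
}


@dataclass(frozen=True)
class BinomialResult:
    """Exact upper-tail binomial prevalence test for one region."""

    region: str
    n_total: int
    k_flagged: int
    p0: float
    p_value: float

    @property
    def proportion(self) -> float:
        return self.k_flagged / self.n_total if self.n_total else 0.0


def binomial_prevalence_test(
    k: int, n: int, p0: float = 0.05, region: str = ""
) -> BinomialResult:
    """Exact one-sided upper-tail binomial test: P(X >= k), X ~ Binomial(n, p0)."""
    if not 0 < p0 < 1:
        raise ValueError("p0 must be in (0, 1)")
    if k < 0 or n < 0 or k > n:
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if n == 0:
        return BinomialResult(region, 0, 0, p0, 1.0)
    p = float(stats.binom.sf(k - 1, n, p0))
    return BinomialResult(region, n, k, p0, p)


def summarize_screening(
    results: pd.DataFrame,
    region_totals: dict[str, int] | None = None,
    p0: float = 0.05,
) -> pd.DataFrame:
    """Per-region screening summary with prevalence tests and a grand total.

    ``results`` is the per-unit screening table (from
    :func:`odorwords.screening.screen_units`).  ``region_totals`` overrides
    the per-region unit counts (defaults to counts observed in the table).
    Regions with zero units get an undefined prevalence p reported as 1.
    Percentages are rounded to integer percent for display; raw proportions
    stay available via the counts.
    """
    if region_totals is None:
        region_totals = results["region"].value_counts().to_dict()
    rows = []
    grand_n = grand_k = grand_inc = grand_dec = 0
    for region in REGIONS:
        if region not in region_totals and (results["region"] == region).sum() == 0:
            continue
        n = int(region_totals.get(region, 0))
        sub = results[results["region"] == region]
        flagged = sub[sub["flagged"]]
        k = len(flagged)
        n_inc = int((flagged["direction"] == "increase").sum())
        n_dec = int((flagged["direction"] == "decrease").sum())
        res = binomial_prevalence_test(k, n, p0, region)
        rows.append(
            {
                "region": region,
                "n_total": n,
                "n_flagged": k,
                "percent": int(round(100 * k / n)) if n else 0,
                "n_increase": n_inc,
                "n_decrease": n_dec,
                "binomial_p": res.p_value,
            }
        )
        grand_n += n
        grand_k += k
        grand_inc += n_inc
        grand_dec += n_dec
    rows.append(
        {
            "region": "total",
            "n_total": grand_n,
            "n_flagged": grand_k,
            "percent": int(round(100 * grand_k / grand_n)) if grand_n else 0,
            "n_increase": grand_inc,
            "n_decrease": grand_dec,
            "binomial_p": np.nan,
        }
    )
    return pd.DataFrame(rows)


def format_p(p: float) -> str:
    """Display rounding for p-values: >= 0.01 to 2-3 decimals, else 4 decimals."""
    if np.isnan(p):
        return ""
    if p < 0.00005:
        return "<0.0001"
    if p >= 0.995:
        return "1.0"
    if p >= 0.2:
        return f"{p:.2f}"
    if p >= 0.01:
        return f"{p:.3f}"
    return f"{p:.4f}"


def render_summary_table(summary: pd.DataFrame, title: str) -> str:
    """Plain-text table mirroring the per-region summary layout."""
    regions = [r for r in summary["region"] if r != "total"]
    cols = [REGION_TITLES.get(r, r) for r in regions]
    rows = {r: summary[summary["region"] == r].iloc[0] for r in regions}
    lines = [title, ""]
    header = ["Number of units"] + cols
    body = [
        ["Total"] + [str(int(rows[r]["n_total"])) for r in regions],
        ["Flagged"]
        + [f"{int(rows[r]['n_flagged'])} ({int(rows[r]['percent'])}%)" for r in regions],
        ["Increase"] + [str(int(rows[r]["n_increase"])) for r in regions],
        ["Decrease"] + [str(int(rows[r]["n_decrease"])) for r in regions],
        ["Binomial test: p-value"] + [format_p(rows[r]["binomial_p"]) for r in regions],
    ]
    widths = [
        max(len(line[i]) for line in [header] + body) for i in range(len(header))
    ]
    for line in [header] + body:
        lines.append("  ".join(s.ljust(w) for s, w in zip(line, widths)).rstrip())
    return "\n".join(lines) + "\n"
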