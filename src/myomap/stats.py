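"""Group comparison of morphometric measurements.

The comparison procedure is fixed: unpaired two-sample t tests across the
stated group contrasts, with Holm-Sidak step-down correction for multiple
comparisons at a family-wise alpha of 0.05.  One correction family is
formed per wall sublayer, mirroring per-layer significance reporting.

The pooled-variance t test is the default (Welch is available as a
flag).  The Holm-Sidak adjustment of sorted p-values p_(1) <= ... <= p_(m)
is

    p'_(i) = 1 - (1 - p_(i)) ** (m - i + 1)

with a running maximum enforcing monotonicity, mapped back to the input
order; a comparison is significant when its adjusted p is below alpha.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .morphometry import ThicknessMeasurementSet

__all__ = [
    "TTestResult",
    "unpaired_t_test",
    "holm_sidak_adjust",
    "compare_thickness_groups",
]


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: float
    p: float


def unpaired_t_test(x, y, equal_var: bool = True) -> TTestResult:
    """Two-sample t test (pooled-variance by default, Welch optional).

    Each sample needs n >= 2 finite values and the samples may not both
    have zero variance.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each sample needs at least 2 observations")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("samples must be finite")
    if x.var(ddof=1) == 0 and y.var(ddof=1) == 0:
        raise ValueError("zero variance in both samples: t is undefined")
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return TTestResult(t=float(res.statistic), df=float(res.df), p=float(res.pvalue))


def holm_sidak_adjust(
    p_values, alpha: float = 0.05
) -> tuple[np.ndarray, np.ndarray]:
    """Holm-Sidak step-down adjusted p-values and significance flags.

    Returns ``(adjusted, significant)`` in the input order;
    ``significant = adjusted < alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or p.size == 0:
        raise ValueError("p_values must be a nonempty 1D sequence")
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = 1.0 - (1.0 - p[order]) ** (m - np.arange(m))
    adj_sorted = np.minimum(np.maximum.accumulate(adj_sorted), 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    return adjusted, adjusted < alpha


_DEFAULT_FACTORS = ("heart", "chamber")


def _default_contrasts(groups: list[tuple]) -> list[tuple[tuple, tuple]]:
    """All pairs of groups differing in exactly one factor level."""
    out = []
    for a, b in itertools.combinations(groups, 2):
        if sum(u != v for u, v in zip(a, b)) == 1:
            out.append((a, b))
    return out


def compare_thickness_groups(
    measurements: ThicknessMeasurementSet | pd.DataFrame,
    alpha: float = 0.05,
    equal_var: bool = True,
) -> pd.DataFrame:
    """Pairwise group comparisons of sublayer thickness with Holm-Sidak.

    Groups are the combinations of the ``heart`` (control/diseased) and
    ``chamber`` (left/right atrium) labels present in the data; within
    each sublayer every pair of groups sharing all but one factor level is
    tested (control vs diseased per chamber, left vs right per heart) and
    the Holm-Sidak correction is applied across that sublayer's family.
    With a single grouping column all pairwise contrasts are used.

    Returns one row per comparison: group labels, per-group n and mean,
    t, degrees of freedom, raw and adjusted p, significance at ``alpha``.
    """
    table = (
        measurements.table
        if isinstance(measurements, ThicknessMeasurementSet)
        else measurements
    )
    factors = [f for f in _DEFAULT_FACTORS if f in table.columns]
    if not factors:
        if "group" in table.columns:
            factors = ["group"]
        else:
            raise ValueError(
                "measurements need group columns ('heart'/'chamber' or 'group')"
            )

    all_groups = {
        key if isinstance(key, tuple) else (key,)
        for key, _ in table.groupby(factors, sort=True)
    }
    rows = []
    for sublayer, sub in table.groupby("sublayer", sort=True):
        samples = {
            key if isinstance(key, tuple) else (key,): g["thickness_um"].to_numpy()
            for key, g in sub.groupby(factors, sort=True)
        }
        groups = sorted(samples)
        absent = sorted(all_groups - set(groups))
        if absent:
            warnings.warn(
                f"{sublayer}: missing group combinations skipped: {absent}",
                stacklevel=2,
            )
        if len(groups) < 2:
            warnings.warn(f"{sublayer}: fewer than two groups; skipped", stacklevel=2)
            continue
        contrasts = (
            _default_contrasts(groups)
            if len(factors) > 1
            else list(itertools.combinations(groups, 2))
        )
        family = []
        for a, b in contrasts:
            xa, xb = samples[a], samples[b]
            if xa.size < 2 or xb.size < 2:
                warnings.warn(
                    f"{sublayer}: {a} vs {b} has a group with n < 2; skipped",
                    stacklevel=2,
                )
                continue
            res = unpaired_t_test(xa, xb, equal_var=equal_var)
            family.append((a, b, xa, xb, res))
        if not family:
            continue
        adjusted, flags = holm_sidak_adjust([f[-1].p for f in family], alpha=alpha)
        for (a, b, xa, xb, res), p_adj, sig in zip(family, adjusted, flags):
            rows.append(
                {
                    "sublayer": sublayer,
                    "group_a": "/".join(map(str, a)),
                    "group_b": "/".join(map(str, b)),
                    "n_a": xa.size,
                    "n_b": xb.size,
                    "mean_a": xa.mean(),
                    "mean_b": xb.mean(),
                    "t": res.t,
                    "df": res.df,
                    "p_raw": res.p,
                    "p_adjusted": p_adj,
                    "significant": bool(sig),
                }
            )
    if not rows:
        raise ValueError("no testable contrasts found")
    return pd.DataFrame(rows)
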