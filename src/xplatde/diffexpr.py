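"""The four differential-expression comparison modes plus Storey FDR.

Modes
-----
``group_t``    a tumor group vs the pooled controls, pooled-variance
               two-sample t-test (Welch optional);
``allvsall_t`` all tumors vs all controls as two unified groups;
``intra_z``    per-sample z-test of each gene's log2 ratio against the
               mean/SD over genes within that sample's column;
``inter_z``    per-gene z-test of each sample's value against that gene's
               mean/SD across samples.

Call tables are pandas DataFrames with columns
``gene_id, unit, mode, statistic, p, q, direction, significant`` where
``unit`` is a sample id, group label or platform id depending on mode.
The significance threshold is strict (``p < alpha``), two-tailed
throughout, and the sample SD uses the n-1 denominator everywhere.
q-values are computed per comparison family (one Storey run per unit or
contrast).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .harmonize import HarmonizedStudy
from .io_formats import ValidationError
from .preprocess import RatioMatrix

MODE_GROUP_T = "group_t"
MODE_ALL_T = "allvsall_t"
MODE_INTRA = "intra_z"
MODE_INTER = "inter_z"

DIR_UP = "up"
DIR_DOWN = "down"
DIR_NONE = "none"

ALL_TUMORS = "ALL"

CALL_COLUMNS = ["gene_id", "unit", "mode", "statistic", "p", "q",
                "direction", "significant"]


@dataclass
class QvalueResult:
    q: np.ndarray
    pi0: float
    lam: float
    m: int


def _new_calls(gene_id, unit, mode, statistic, p) -> pd.DataFrame:
    calls = pd.DataFrame(
        {
            "gene_id": np.asarray(gene_id, dtype=int),
            "unit": unit,
            "mode": mode,
            "statistic": np.asarray(statistic, dtype=float),
            "p": np.asarray(p, dtype=float),
        }
    )
    calls["q"] = np.nan
    calls["direction"] = DIR_NONE
    calls["significant"] = False
    return calls


# ---------------------------------------------------------------------------
# t-test modes
# ---------------------------------------------------------------------------

def _two_sample_t(a: np.ndarray, b: np.ndarray, equal_var: bool
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise two-sample t with NaN exclusion and degenerate handling.

    Zero pooled variance with equal means -> t=0, p=1 by convention; with
    unequal means -> t=+/-inf, p=0 (flagged in-band as an extreme).
    """
    with warnings.catch_warnings():
        # constant rows trigger scipy's precision-loss warning; they are
        # handled explicitly below
        warnings.simplefilter("ignore", RuntimeWarning)
        res = stats.ttest_ind(a, b, axis=1, equal_var=equal_var,
                              nan_policy="omit")
    t = np.asarray(res.statistic, dtype=float)
    p = np.asarray(res.pvalue, dtype=float)
    mean_diff = np.nanmean(a, axis=1) - np.nanmean(b, axis=1)
    degenerate = ~np.isfinite(t)
    zero_diff = np.isclose(mean_diff, 0.0)
    t[degenerate & zero_diff] = 0.0
    p[degenerate & zero_diff] = 1.0
    still = degenerate & ~zero_diff
    t[still] = np.sign(mean_diff[still]) * np.inf
    p[still] = 0.0
    return t, p


def group_vs_controls_ttest(
    h: HarmonizedStudy,
    group: str = ALL_TUMORS,
    alpha: float = 0.05,
    equal_var: bool = True,
    tumor_sample_ids: list[str] | None = None,
) -> pd.DataFrame:
    """Two-tailed two-sample t-test of a tumor group against all controls.

    ``group=ALL`` compares every tumor sample as one unified group.
    ``tumor_sample_ids`` overrides the tumor side (used for per-platform
    contrasts); the unit label is then the supplied ``group`` tag.
    Direction is the sign of (group mean - control mean) when significant.
    """
    frame = h.to_frame()
    controls = h.control_sample_ids()
    if len(controls) < 2:
        raise ValidationError("need at least two control samples")
    if tumor_sample_ids is not None:
        tumors = list(tumor_sample_ids)
        mode = MODE_GROUP_T
    elif group == ALL_TUMORS:
        tumors = h.tumor_sample_ids()
        mode = MODE_ALL_T
    else:
        if group not in h.groups:
            raise ValidationError(f"unknown group {group!r}")
        tumors = sorted(h.groups[group])
        mode = MODE_GROUP_T
    if len(tumors) < 2:
        raise ValidationError(f"group {group!r} has fewer than two samples")
    t, p = _two_sample_t(frame[tumors].to_numpy(), frame[controls].to_numpy(),
                         equal_var)
    calls = _new_calls(frame.index.to_numpy(), group, mode, t, p)
    return call_de(calls, alpha)


def all_groups_ttests(h: HarmonizedStudy, alpha: float = 0.05,
                      equal_var: bool = True) -> pd.DataFrame:
    """One group-vs-controls contrast per non-empty tumor group."""
    parts = [
        group_vs_controls_ttest(h, group=g, alpha=alpha, equal_var=equal_var)
        for g in sorted(h.groups)
        if len(h.groups[g]) >= 2
    ]
    if not parts:
        raise ValidationError("no group has two or more samples")
    return pd.concat(parts, ignore_index=True)


def per_platform_ttests(h: HarmonizedStudy, alpha: float = 0.05,
                        equal_var: bool = True) -> pd.DataFrame:
    """Each platform's tumors vs the pooled controls; unit = platform id."""
    tumors_by_platform: dict[str, list[str]] = {}
    for s in h.tumor_sample_ids():
        tumors_by_platform.setdefault(h.platform_of[s], []).append(s)
    parts = [
        group_vs_controls_ttest(h, group=pid, alpha=alpha, equal_var=equal_var,
                                tumor_sample_ids=samples)
        for pid, samples in sorted(tumors_by_platform.items())
        if len(samples) >= 2
    ]
    if not parts:
        raise ValidationError("no platform has two or more tumor samples")
    return pd.concat(parts, ignore_index=True)


# ---------------------------------------------------------------------------
# z-test modes
# ---------------------------------------------------------------------------

def intra_experimental_ztest(
    ratios: RatioMatrix, sample: str | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-sample z-test: standardize each gene against the mean/SD over
    genes within that sample's column (``None`` -> all samples)."""
    frame = ratios.to_frame()
    samples = [sample] if sample is not None else list(frame.columns)
    parts = []
    for s in samples:
        if s not in frame.columns:
            raise ValidationError(f"unknown sample {s!r}")
        col = frame[s]
        ok = col.notna()
        if int(ok.sum()) < 3:
            raise ValidationError(f"sample {s!r} has fewer than 3 unmasked genes")
        mu = float(col[ok].mean())
        sd = float(col[ok].std(ddof=1))
        if sd == 0:
            raise ValidationError(f"sample {s!r} has zero SD across genes")
        z = (col - mu) / sd
        p = 2.0 * stats.norm.sf(np.abs(z.to_numpy()))
        parts.append(_new_calls(frame.index.to_numpy(), s, MODE_INTRA,
                                z.to_numpy(), p))
    return call_de(pd.concat(parts, ignore_index=True), alpha)


def inter_experimental_ztest(
    ratios: RatioMatrix, gene: int | None = None, alpha: float = 0.05
) -> pd.DataFrame:
    """Per-gene z-test: standardize each sample's value against that gene's
    mean/SD across samples.  A constant gene row is 'inter-unchanged':
    z=0, p=1 for every sample."""
    frame = ratios.to_frame()
    if gene is not None:
        if gene not in frame.index:
            raise ValidationError(f"unknown gene {gene!r}")
        frame = frame.loc[[gene]]
    x = frame.to_numpy(dtype=float)
    n_ok = np.isfinite(x).sum(axis=1)
    if (n_ok < 3).any():
        bad = frame.index[np.nonzero(n_ok < 3)[0][0]]
        raise ValidationError(f"gene {bad!r} has fewer than 3 unmasked samples")
    mu = np.nanmean(x, axis=1)
    sd = np.nanstd(x, axis=1, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        z = (x - mu[:, None]) / sd[:, None]
    z[sd == 0, :] = 0.0
    p = 2.0 * stats.norm.sf(np.abs(z))
    p[sd == 0, :] = 1.0
    p[~np.isfinite(x)] = np.nan
    z[~np.isfinite(x)] = np.nan
    rows = np.repeat(frame.index.to_numpy(), len(frame.columns))
    units = np.tile(np.asarray(frame.columns, dtype=object), len(frame.index))
    calls = _new_calls(rows, units, MODE_INTER, z.ravel(), p.ravel())
    return call_de(calls, alpha)


# ---------------------------------------------------------------------------
# Storey q-values
# ---------------------------------------------------------------------------

def storey_qvalues(p, lam: float = 0.5) -> QvalueResult:
    """Storey q-values with a fixed pi0 tuning parameter.

    pi0 = #{p > lam} / (m (1 - lam)), clamped to (1/m, 1]; then the
    step-down rule q(p_(i)) = min_{j>=i} pi0 m p_(j) / j, clamped to
    [p, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise ValidationError("empty p-value vector")
    if np.nanmin(p) < 0 or np.nanmax(p) > 1:
        raise ValidationError("p-values must lie in [0, 1]")
    if not (0.0 <= lam < 1.0):
        raise ValidationError("lambda must lie in [0, 1)")
    m = p.size
    pi0 = (p > lam).sum() / (m * (1.0 - lam))
    pi0 = float(min(1.0, max(pi0, 1.0 / m)))
    order = np.argsort(p, kind="stable")
    ranks = np.arange(1, m + 1)
    q_sorted = pi0 * m * p[order] / ranks
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = q_sorted
    q = np.clip(q, p, 1.0)
    return QvalueResult(q=q, pi0=pi0, lam=lam, m=m)


def add_qvalues(calls: pd.DataFrame, lam: float = 0.5) -> pd.DataFrame:
    """Attach q-values, one Storey run per comparison family (per unit)."""
    calls = calls.copy()
    for _, idx in calls.groupby("unit", sort=False).groups.items():
        p = calls.loc[idx, "p"].to_numpy()
        ok = np.isfinite(p)
        if ok.sum() == 0:
            continue
        q = np.full(p.size, np.nan)
        q[ok] = storey_qvalues(p[ok], lam=lam).q
        calls.loc[idx, "q"] = q
    return calls


# ---------------------------------------------------------------------------
# thresholding
# ---------------------------------------------------------------------------

def call_de(calls: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """significant iff p < alpha (strict); direction from the statistic's sign."""
    if not (0.0 < alpha < 1.0):
        raise ValidationError("alpha must lie in (0, 1)")
    calls = calls.copy()
    sig = calls["p"].to_numpy() < alpha
    stat = calls["statistic"].to_numpy()
    direction = np.where(sig & (stat > 0), DIR_UP,
                         np.where(sig & (stat < 0), DIR_DOWN, DIR_NONE))
    calls["significant"] = sig
    calls["direction"] = direction
    calls.attrs["alpha"] = alpha
    return calls
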