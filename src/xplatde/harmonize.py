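"""Cross-platform harmonization.

Builds the common gene list (intersection of per-platform NCBI Gene IDs),
quantile cross-normalizes all samples to a shared empirical distribution,
and assembles the tumor-group structure.  Normalization operates on the
log2-ratio scale; already-normalized public-style studies enter here
directly without the raw preprocessing stage.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import (
    CLS_CONTROL,
    CLS_TUMOR,
    GeneAnnotation,
    SampleMeta,
    ValidationError,
)
from .preprocess import RatioMatrix


@dataclass
class HarmonizedStudy:
    """Cross-platform log2-ratio matrix restricted to the common gene list."""

    gene_ids: list[int]
    values: np.ndarray               # genes x all samples
    sample_ids: list[str]
    meta: list[SampleMeta]
    groups: dict[str, set[str]]      # group label -> tumor sample ids
    platform_of: dict[str, str]      # sample id -> platform id

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("harmonized matrix shape mismatch")
        tumor_ids = {m.sample_id for m in self.meta if m.cls == CLS_TUMOR
                     and m.sample_id in set(self.sample_ids)}
        covered: set[str] = set()
        for label, members in self.groups.items():
            if covered & members:
                raise ValidationError(f"group {label!r} overlaps another group")
            covered |= members
        if covered != tumor_ids:
            raise ValidationError("groups do not partition the tumor samples")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.sample_ids)

    def control_sample_ids(self) -> list[str]:
        in_study = set(self.sample_ids)
        return [m.sample_id for m in self.meta
                if m.cls == CLS_CONTROL and m.sample_id in in_study]

    def tumor_sample_ids(self) -> list[str]:
        in_study = set(self.sample_ids)
        return [m.sample_id for m in self.meta
                if m.cls == CLS_TUMOR and m.sample_id in in_study]

    def tumor_ratio_matrix(self) -> RatioMatrix:
        """Tumor columns as a RatioMatrix view (for the per-sample z modes)."""
        tumors = self.tumor_sample_ids()
        frame = self.to_frame()[tumors]
        return RatioMatrix.from_frame(frame)


# ---------------------------------------------------------------------------
# operations
# ---------------------------------------------------------------------------

def build_common_gene_list(annotations: list[GeneAnnotation]) -> list[int]:
    """Intersection of per-platform Gene-ID sets, sorted ascending."""
    if len(annotations) < 2:
        raise ValidationError("need at least two platforms to intersect")
    common = set(annotations[0].gene_ids)
    for ann in annotations[1:]:
        common &= ann.gene_ids
    if not common:
        raise ValidationError("no gene is present on every platform")
    return sorted(common)


def quantile_normalize_frame(frame: pd.DataFrame) -> pd.DataFrame:
    """Force all columns to share the mean-of-sorted-columns distribution.

    Each column is replaced by the reference distribution mapped back
    through its ranks; tied values receive the mean of the reference
    values over the tied rank span.  Columns with masked (NaN) entries are
    mapped through interpolated quantiles of their non-missing values, so
    the identical-sorted-multiset guarantee holds exactly only for
    complete columns.
    """
    x = frame.to_numpy(dtype=float)
    n, m = x.shape
    if m == 0 or n == 0:
        raise ValidationError("empty matrix")
    grid = np.linspace(0.0, 1.0, n)
    ref = np.zeros(n)
    for j in range(m):
        col = x[:, j]
        v = np.sort(col[np.isfinite(col)])
        if v.size == 0:
            raise ValidationError(f"column {frame.columns[j]!r} is entirely masked")
        if v.size == n:
            ref += v
        else:
            ref += np.interp(grid, np.linspace(0.0, 1.0, v.size), v)
    ref /= m

    out = np.full_like(x, np.nan)
    for j in range(m):
        col = x[:, j]
        ok = np.isfinite(col)
        vals = col[ok]
        k = vals.size
        order = np.argsort(vals, kind="stable")
        if k == n:
            assigned = np.empty(k)
            assigned[order] = ref
        else:
            assigned = np.empty(k)
            assigned[order] = np.interp(
                np.linspace(0.0, 1.0, k), grid, ref
            )
        # ties: average the assigned reference values over each tied span
        s = pd.Series(assigned).groupby(pd.Series(vals)).transform("mean")
        res = np.empty(k)
        res[:] = s.to_numpy()
        out[ok, j] = res
    return pd.DataFrame(out, index=frame.index, columns=frame.columns)


def quantile_cross_normalize(
    ratio_matrices: list[RatioMatrix],
    meta: list[SampleMeta],
    group_spec: list[str] | tuple[str, ...],
    common_genes: list[int] | None = None,
) -> HarmonizedStudy:
    """Quantile-normalize gene-level ratio matrices into one pooled study.

    All matrices must already be keyed by Gene ID; they are restricted to
    ``common_genes`` (default: the intersection of their row sets) before
    the joint normalization.
    """
    if not ratio_matrices:
        raise ValidationError("no studies to harmonize")
    frames = [r.to_frame() for r in ratio_matrices]
    if common_genes is None:
        common: set = set(frames[0].index)
        for f in frames[1:]:
            common &= set(f.index)
        if not common:
            raise ValidationError("no gene is present on every platform")
        common_genes = sorted(common)
    for f in frames:
        missing = set(common_genes) - set(f.index)
        if missing:
            raise ValidationError(
                f"study lacks {len(missing)} common genes (e.g. {sorted(missing)[:3]})"
            )
    joined = pd.concat([f.loc[common_genes] for f in frames], axis=1)
    if joined.columns.duplicated().any():
        raise ValidationError("duplicate sample ids across studies")
    normalized = quantile_normalize_frame(joined)

    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in normalized.columns if s not in by_id]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:3]}")
    in_study = [by_id[s] for s in normalized.columns]
    groups = assign_groups(in_study, group_spec)
    return HarmonizedStudy(
        gene_ids=[int(g) for g in common_genes],
        values=normalized.to_numpy(),
        sample_ids=[str(c) for c in normalized.columns],
        meta=in_study,
        groups=groups,
        platform_of={m.sample_id: m.platform_id for m in in_study},
    )


def assign_groups(
    meta: list[SampleMeta], group_spec: list[str] | tuple[str, ...]
) -> dict[str, set[str]]:
    """Disjoint cover of the tumor samples by the configured group labels."""
    groups: dict[str, set[str]] = {g: set() for g in group_spec}
    for m in meta:
        if m.cls != CLS_TUMOR:
            continue
        if m.group not in groups:
            raise ValidationError(
                f"tumor sample {m.sample_id!r} has unknown group {m.group!r}"
            )
        groups[m.group].add(m.sample_id)
    return groups
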