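"""Single-channel (CodeLink-style) raw-spot preprocessing.

Pipeline order is fixed: flag low signals -> background-correct ->
intensity cutoff -> global-median normalize -> log2 ratios against the
control mean.  Everything here is deterministic; no RNG is involved.

The flagging rule marks a spot when its signal S falls below
``B_L + k_sigma * sigma_BL`` (local background plus a multiple of its SD).
The multiplier defaults to the conventional CodeLink value 1.5 and is
configurable.  Background correction subtracts the offset between the
array's median local background and its global background median from
each signal (a direct local-background subtraction is available as an
alternative mode), flooring at a small positive value so intensities stay
positive.  The cutoff flags spots whose corrected signal is below
``cutoff_fold`` times the median local background; a spot exactly at the
threshold is retained.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .io_formats import (
    CLS_CONTROL,
    CLS_TUMOR,
    SCALE_INTENSITY,
    SCALE_LOG2RATIO,
    ExpressionStudy,
    GeneAnnotation,
    SampleMeta,
    ValidationError,
)

FLAG_OK = "ok"
FLAG_LOW = "low_signal"
FLAG_CUTOFF = "below_cutoff"

BG_MODE_OFFSET = "offset"  # subtract (median local bg - global bg)
BG_MODE_LOCAL = "local"    # subtract each spot's own local background


@dataclass
class RawSpotTable:
    """Per-spot channels for one array, pre-normalization."""

    array_id: str
    probe_ids: list[str]
    signal: np.ndarray          # S, measured signal intensity
    local_bg: np.ndarray        # B_L
    local_bg_sd: np.ndarray     # sigma_BL
    global_bg: float            # B_G, one median per array
    flags: np.ndarray           # dtype object/str, one of the FLAG_* values

    def __post_init__(self) -> None:
        n = len(self.probe_ids)
        self.signal = np.asarray(self.signal, dtype=float)
        self.local_bg = np.asarray(self.local_bg, dtype=float)
        self.local_bg_sd = np.asarray(self.local_bg_sd, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        for name in ("signal", "local_bg", "local_bg_sd", "flags"):
            if getattr(self, name).shape != (n,):
                raise ValidationError(f"{name} length does not match probe count")
        if len(set(self.probe_ids)) != n:
            raise ValidationError("duplicate probe ids in raw spot table")
        if (self.local_bg_sd < 0).any():
            raise ValidationError("negative local background SD")
        if (self.signal < 0).any() or (self.local_bg < 0).any():
            raise ValidationError("negative intensity channel")

    @property
    def n_spots(self) -> int:
        return len(self.probe_ids)

    def analyzable(self) -> np.ndarray:
        return self.flags == FLAG_OK


@dataclass(frozen=True)
class PreprocessConfig:
    k_sigma: float = 1.5
    cutoff_fold: float = 2.0
    floor: float = 1.0
    background_mode: str = BG_MODE_OFFSET

    def __post_init__(self) -> None:
        if self.k_sigma <= 0 or self.cutoff_fold <= 0 or self.floor <= 0:
            raise ValidationError("preprocess thresholds must be positive")
        if self.background_mode not in (BG_MODE_OFFSET, BG_MODE_LOCAL):
            raise ValidationError(f"unknown background mode {self.background_mode!r}")


@dataclass
class RatioMatrix:
    """log2(tumor / mean of controls) per gene (or probe) and tumor sample."""

    gene_ids: list
    log2_ratios: np.ndarray      # genes x tumor samples, NaN = masked
    sample_ids: list[str]
    control_mean: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.log2_ratios = np.asarray(self.log2_ratios, dtype=float)
        if self.log2_ratios.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValidationError("ratio matrix shape mismatch")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.log2_ratios, index=self.gene_ids, columns=self.sample_ids
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   control_mean: np.ndarray | None = None) -> "RatioMatrix":
        return cls(
            gene_ids=list(frame.index),
            log2_ratios=frame.to_numpy(),
            sample_ids=[str(c) for c in frame.columns],
            control_mean=control_mean,
        )


# ---------------------------------------------------------------------------
# raw-spot operations
# ---------------------------------------------------------------------------

def flag_low_signal(table: RawSpotTable, config: PreprocessConfig) -> RawSpotTable:
    """Flag spots with S < B_L + k_sigma * sigma_BL; other flags unchanged."""
    threshold = table.local_bg + config.k_sigma * table.local_bg_sd
    low = table.signal < threshold
    flags = table.flags.copy()
    flags[low] = FLAG_LOW
    return replace(table, flags=flags)


def background_correct(table: RawSpotTable, config: PreprocessConfig) -> RawSpotTable:
    """Subtract the array's background offset from every signal.

    Default mode: corrected S = max(floor, S - (median(B_L) - B_G)).
    ``local`` mode subtracts each spot's own local background instead.
    """
    if not table.analyzable().any():
        raise ValidationError(f"array {table.array_id!r} has no unflagged spots")
    if config.background_mode == BG_MODE_OFFSET:
        offset = float(np.median(table.local_bg)) - table.global_bg
        corrected = table.signal - offset
    else:
        corrected = table.signal - table.local_bg
    corrected = np.maximum(config.floor, corrected)
    return replace(table, signal=corrected)


def apply_intensity_cutoff(table: RawSpotTable, config: PreprocessConfig) -> RawSpotTable:
    """Flag spots whose corrected signal is below cutoff_fold x median(B_L).

    A spot exactly at the threshold is retained (inclusive comparison).
    """
    threshold = config.cutoff_fold * float(np.median(table.local_bg))
    below = (table.signal < threshold) & (table.flags == FLAG_OK)
    flags = table.flags.copy()
    flags[below] = FLAG_CUTOFF
    return replace(table, flags=flags)


def preprocess_raw_arrays(
    tables: list[RawSpotTable], config: PreprocessConfig, platform_id: str
) -> tuple[ExpressionStudy, pd.DataFrame]:
    """Run flag -> correct -> cutoff on each array and assemble a study.

    Flagged spots become masked (NaN) entries.  Returns the intensity-scale
    study plus a per-array flag summary (counts per flag value).
    """
    if not tables:
        raise ValidationError("no raw arrays supplied")
    probe_ids = tables[0].probe_ids
    for t in tables[1:]:
        if t.probe_ids != probe_ids:
            raise ValidationError("raw arrays do not share a probe list")
    values = np.full((len(probe_ids), len(tables)), np.nan)
    summary_rows = []
    for j, t in enumerate(tables):
        t = flag_low_signal(t, config)
        t = background_correct(t, config)
        t = apply_intensity_cutoff(t, config)
        ok = t.analyzable()
        values[ok, j] = t.signal[ok]
        counts = pd.Series(t.flags).value_counts()
        summary_rows.append(
            {
                "array_id": t.array_id,
                FLAG_OK: int(counts.get(FLAG_OK, 0)),
                FLAG_LOW: int(counts.get(FLAG_LOW, 0)),
                FLAG_CUTOFF: int(counts.get(FLAG_CUTOFF, 0)),
            }
        )
    study = ExpressionStudy(
        platform_id=platform_id,
        probe_ids=list(probe_ids),
        values=values,
        sample_ids=[t.array_id for t in tables],
        scale=SCALE_INTENSITY,
    )
    return study, pd.DataFrame(summary_rows).set_index("array_id")


# ---------------------------------------------------------------------------
# normalization and ratios
# ---------------------------------------------------------------------------

def global_median_normalize(study: ExpressionStudy) -> ExpressionStudy:
    """Divide each array by the median of its analyzable (unmasked) spots."""
    if study.scale != SCALE_INTENSITY:
        raise ValidationError("global median normalization requires intensity scale")
    values = study.values.copy()
    for j, sid in enumerate(study.sample_ids):
        col = values[:, j]
        med = np.nanmedian(col)
        if not np.isfinite(med) or med <= 0:
            raise ValidationError(f"sample {sid!r} has non-positive median")
        values[:, j] = col / med
    return ExpressionStudy(
        platform_id=study.platform_id,
        probe_ids=list(study.probe_ids),
        values=values,
        sample_ids=list(study.sample_ids),
        scale=SCALE_INTENSITY,
    )


def compute_log_ratios(
    study: ExpressionStudy, meta: list[SampleMeta], include_controls: bool = False
) -> RatioMatrix:
    """log2(tumor value / arithmetic mean of control values) per gene.

    Entries are masked wherever an operand is masked or non-positive.
    With ``include_controls`` every sample (controls too) is expressed as
    a ratio against the control mean, which keeps control columns
    available for downstream group-vs-control contrasts on a common
    scale; control ratios then scatter around zero.
    """
    if study.scale != SCALE_INTENSITY:
        raise ValidationError("log ratios are computed from intensity data")
    by_id = {m.sample_id: m for m in meta}
    missing = [s for s in study.sample_ids if s not in by_id]
    if missing:
        raise ValidationError(f"samples without metadata: {missing[:3]}")
    control_idx = [
        j for j, s in enumerate(study.sample_ids) if by_id[s].cls == CLS_CONTROL
    ]
    if include_controls:
        tumor_idx = list(range(len(study.sample_ids)))
    else:
        tumor_idx = [
            j for j, s in enumerate(study.sample_ids) if by_id[s].cls == CLS_TUMOR
        ]
    if not control_idx:
        raise ValidationError(f"study {study.platform_id!r} has no control samples")
    controls = study.values[:, control_idx]
    with np.errstate(invalid="ignore"):
        control_mean = np.nanmean(controls, axis=1)
    tumors = study.values[:, tumor_idx]
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = np.log2(tumors / control_mean[:, None])
    bad = (
        ~np.isfinite(tumors)
        | (tumors <= 0)
        | ~np.isfinite(control_mean[:, None])
        | (control_mean[:, None] <= 0)
    )
    ratios[bad] = np.nan
    return RatioMatrix(
        gene_ids=list(study.probe_ids),
        log2_ratios=ratios,
        sample_ids=[study.sample_ids[j] for j in tumor_idx],
        control_mean=control_mean,
    )


def collapse_probes(ratios: RatioMatrix, annotation: GeneAnnotation) -> RatioMatrix:
    """Collapse probe-level rows to Gene-ID rows by median log ratio.

    Probes absent from the annotation are dropped (they cannot enter the
    common gene list).  Applied after ratio computation so the collapse is
    order-independent and robust to outlier probes.
    """
    probe_to_gene = annotation.probe_to_gene()
    frame = ratios.to_frame()
    keep = frame.index.isin(probe_to_gene.index)
    frame = frame.loc[keep]
    genes = probe_to_gene.reindex(frame.index)
    collapsed = frame.groupby(genes.to_numpy()).median()
    collapsed.index = collapsed.index.astype(int)
    collapsed = collapsed.sort_index()
    return RatioMatrix.from_frame(collapsed)
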