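"""Multi-platform synthetic microarray studies with planted ground truth.

The default configuration emulates the pooled bladder-cancer design the
pipeline targets: three single-channel platforms measuring overlapping
subsets of a shared gene universe, 17 control and 129 tumor arrays, the
tumors partitioned into 11 stage/grade groups, a small core of genes
up- or down-regulated simultaneously in every tumor, plus group-specific
differential genes, on a log-normal intensity baseline with
platform-specific location/scale effects.

All randomness flows from ``SimulationConfig.seed`` through a fixed tree
of ``numpy`` seed sequences, so each generator is byte-reproducible and
the annotation/term generator agrees with the expression generator about
the planted truth.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import (
    CHROMOSOMES,
    CLS_CONTROL,
    CLS_TUMOR,
    SCALE_INTENSITY,
    ExpressionStudy,
    GeneAnnotation,
    SampleMeta,
    TermSet,
    ValidationError,
)
from .preprocess import FLAG_OK, RawSpotTable

#: default 11 tumor stage/grade groups
DEFAULT_GROUPS: tuple[str, ...] = (
    "Ta-GradeI", "Ta-GradeII", "Ta-GradeIII",
    "T1-GradeI", "T1-GradeII", "T1-GradeIII",
    "T2-GradeII", "T2-GradeIII", "T3-GradeII", "T3-GradeIII",
    "Tis",
)

# child indices of the root SeedSequence; fixed so independent generator
# calls with the same seed agree about truth/annotation
_SS_TRUTH, _SS_BASELINE, _SS_CHROM, _SS_TERMS, _SS_RAW, _SS_PLATFORM0 = range(6)


@dataclass(frozen=True)
class PlatformSpec:
    platform_id: str
    probe_subset_fraction: float
    n_controls: int
    n_tumors: int
    shift: float = 0.0   # additive log2 location effect
    scale: float = 1.0   # multiplicative effect on the log2 baseline

    def __post_init__(self) -> None:
        if not (0.0 < self.probe_subset_fraction <= 1.0):
            raise ValidationError("probe_subset_fraction must be in (0, 1]")
        if self.n_controls < 0 or self.n_tumors < 0:
            raise ValidationError("sample counts must be non-negative")


@dataclass(frozen=True)
class SimulationConfig:
    """Knobs of the synthetic study; defaults are the study conditions."""

    n_genes_universe: int = 2000
    platforms: tuple[PlatformSpec, ...] = (
        PlatformSpec("chipA", 0.95, 5, 10, shift=0.0, scale=1.0),
        PlatformSpec("chipB", 0.90, 9, 60, shift=0.6, scale=1.1),
        PlatformSpec("chipC", 0.90, 3, 59, shift=-0.4, scale=0.9),
    )
    groups: tuple[str, ...] = DEFAULT_GROUPS
    n_common_up: int = 30
    n_common_down: int = 80
    effect_common: float = 1.0       # mean |log2 shift|, = 2 x noise_sd
    n_group_specific: int = 5        # per group
    effect_group: float = 1.0
    noise_sd: float = 0.5            # SD of log2 measurement noise
    baseline_log2_mean: float = 8.0
    baseline_log2_sd: float = 1.0
    # raw-spot layer
    n_spots_raw: int = 0             # 0 -> use platform 0's probe count
    fraction_low: float = 0.05       # spots planted below the flag threshold
    k_sigma_raw: float = 1.5
    # annotation/term layer
    chromosome_weights: tuple[float, ...] | None = None  # None -> uniform
    n_terms: int = 50
    term_size_range: tuple[int, int] = (10, 50)
    n_enriched_terms: int = 1
    enriched_term_size: int = 20
    enriched_overlap: int = 15       # members drawn from the planted common set
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_genes_universe <= 0:
            raise ValidationError("universe must be non-empty")
        if min(self.n_common_up, self.n_common_down, self.n_group_specific) < 0:
            raise ValidationError("planted counts must be non-negative")
        planted = (
            self.n_common_up
            + self.n_common_down
            + self.n_group_specific * len(self.groups)
        )
        if planted > self.n_genes_universe:
            raise ValidationError(
                f"{planted} planted genes exceed universe of {self.n_genes_universe}"
            )
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")
        if not (0.0 <= self.fraction_low < 1.0):
            raise ValidationError("fraction_low must be in [0, 1)")
        if self.enriched_overlap > self.enriched_term_size:
            raise ValidationError("enriched_overlap exceeds the term size")
        if self.chromosome_weights is not None and (
            len(self.chromosome_weights) != len(CHROMOSOMES)
            or min(self.chromosome_weights) < 0
        ):
            raise ValidationError("chromosome_weights must be 25 non-negative values")

    @property
    def n_controls_total(self) -> int:
        return sum(p.n_controls for p in self.platforms)

    @property
    def n_tumors_total(self) -> int:
        return sum(p.n_tumors for p in self.platforms)


@dataclass(frozen=True)
class GroundTruth:
    common_up: frozenset[int]
    common_down: frozenset[int]
    group_specific: dict[str, frozenset[int]]
    null_genes: frozenset[int]

    def __post_init__(self) -> None:
        sets = [self.common_up, self.common_down, *self.group_specific.values()]
        union: set[int] = set()
        total = 0
        for s in sets:
            union |= s
            total += len(s)
        if len(union) != total:
            raise ValidationError("planted gene sets are not disjoint")
        if union & self.null_genes:
            raise ValidationError("planted genes overlap the null set")

    def labels(self) -> dict[int, str]:
        out = {g: "common_up" for g in self.common_up}
        out.update({g: "common_down" for g in self.common_down})
        for grp, genes in self.group_specific.items():
            out.update({g: f"group:{grp}" for g in genes})
        out.update({g: "null" for g in self.null_genes})
        return out


# ---------------------------------------------------------------------------
# deterministic sub-streams
# ---------------------------------------------------------------------------

def _children(config: SimulationConfig) -> list[np.random.SeedSequence]:
    n = _SS_PLATFORM0 + len(config.platforms)
    return np.random.SeedSequence(config.seed).spawn(n)


def _rng(config: SimulationConfig, index: int) -> np.random.Generator:
    return np.random.default_rng(_children(config)[index])


def _universe(config: SimulationConfig) -> np.ndarray:
    # NCBI-style positive integer ids, stable for a given universe size
    return np.arange(1001, 1001 + config.n_genes_universe, dtype=int)


def _plant_truth(config: SimulationConfig) -> GroundTruth:
    rng = _rng(config, _SS_TRUTH)
    universe = _universe(config)
    perm = rng.permutation(universe)
    pos = 0
    common_up = frozenset(int(g) for g in perm[pos:pos + config.n_common_up])
    pos += config.n_common_up
    common_down = frozenset(int(g) for g in perm[pos:pos + config.n_common_down])
    pos += config.n_common_down
    group_specific: dict[str, frozenset[int]] = {}
    for grp in config.groups:
        group_specific[grp] = frozenset(
            int(g) for g in perm[pos:pos + config.n_group_specific]
        )
        pos += config.n_group_specific
    null_genes = frozenset(int(g) for g in perm[pos:])
    return GroundTruth(common_up, common_down, group_specific, null_genes)


def _sample_allocation(config: SimulationConfig) -> list[SampleMeta]:
    """Controls then tumors per platform; groups cycle over the global tumor index."""
    meta: list[SampleMeta] = []
    tumor_counter = 0
    for spec in config.platforms:
        for i in range(spec.n_controls):
            meta.append(
                SampleMeta(f"{spec.platform_id}_C{i + 1:02d}", spec.platform_id,
                           CLS_CONTROL, "")
            )
        for i in range(spec.n_tumors):
            group = config.groups[tumor_counter % len(config.groups)]
            meta.append(
                SampleMeta(f"{spec.platform_id}_T{i + 1:03d}", spec.platform_id,
                           CLS_TUMOR, group)
            )
            tumor_counter += 1
    return meta


def _platform_probes(
    config: SimulationConfig, spec: PlatformSpec, truth: GroundTruth,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gene ids measured on this platform.

    Planted genes are always measured on every platform so the ground
    truth stays identifiable after the cross-platform intersection; the
    probe subset fraction thins only null genes.
    """
    universe = _universe(config)
    n_probes = int(round(spec.probe_subset_fraction * len(universe)))
    planted = sorted(set(universe.tolist()) - set(truth.null_genes))
    n_extra = max(0, n_probes - len(planted))
    nulls = np.array(sorted(truth.null_genes), dtype=int)
    extra = rng.choice(nulls, size=min(n_extra, len(nulls)), replace=False)
    genes = np.sort(np.concatenate([np.asarray(planted, dtype=int), extra]))
    return genes


def _chromosome_assignment(config: SimulationConfig) -> pd.Series:
    rng = _rng(config, _SS_CHROM)
    universe = _universe(config)
    if config.chromosome_weights is None:
        probs = None
    else:
        w = np.asarray(config.chromosome_weights, dtype=float)
        probs = w / w.sum()
    chroms = rng.choice(np.asarray(CHROMOSOMES, dtype=object),
                        size=len(universe), p=probs)
    return pd.Series(chroms, index=universe, name="chromosome")


# ---------------------------------------------------------------------------
# generators
# ---------------------------------------------------------------------------

def generate_multiplatform_study(
    config: SimulationConfig,
) -> tuple[list[ExpressionStudy], list[SampleMeta], list[GeneAnnotation], GroundTruth]:
    """Generate intensity-scale studies for every platform plus metadata.

    The log2 intensity of gene g on sample s of platform p is

        shift_p + scale_p * b_g + effect(g, s) + N(0, noise_sd)

    with baseline b_g ~ N(baseline_log2_mean, baseline_log2_sd), effect
    +effect_common for planted-up genes in every tumor, -effect_common for
    planted-down genes, and +effect_group for a group's genes in that
    group's tumors only.  Intensities are 2 to that power.
    """
    truth = _plant_truth(config)
    meta = _sample_allocation(config)
    baseline = pd.Series(
        _rng(config, _SS_BASELINE).normal(
            config.baseline_log2_mean, config.baseline_log2_sd,
            size=config.n_genes_universe,
        ),
        index=_universe(config),
    )
    chrom = _chromosome_assignment(config)
    up = np.array(sorted(truth.common_up), dtype=int)
    down = np.array(sorted(truth.common_down), dtype=int)

    studies: list[ExpressionStudy] = []
    annotations: list[GeneAnnotation] = []
    meta_by_platform: dict[str, list[SampleMeta]] = {}
    for m in meta:
        meta_by_platform.setdefault(m.platform_id, []).append(m)

    for k, spec in enumerate(config.platforms):
        rng = _rng(config, _SS_PLATFORM0 + k)
        genes = _platform_probes(config, spec, truth, rng)
        gene_pos = {g: i for i, g in enumerate(genes)}
        b = baseline.loc[genes].to_numpy()
        samples = meta_by_platform.get(spec.platform_id, [])
        log2x = np.empty((len(genes), len(samples)))
        for j, m in enumerate(samples):
            effect = np.zeros(len(genes))
            if m.cls == CLS_TUMOR:
                effect[[gene_pos[g] for g in up if g in gene_pos]] += config.effect_common
                effect[[gene_pos[g] for g in down if g in gene_pos]] -= config.effect_common
                for g in truth.group_specific.get(m.group, ()):
                    if g in gene_pos:
                        effect[gene_pos[g]] += config.effect_group
            noise = rng.normal(0.0, config.noise_sd, size=len(genes))
            log2x[:, j] = spec.shift + spec.scale * b + effect + noise
        studies.append(
            ExpressionStudy(
                platform_id=spec.platform_id,
                probe_ids=[f"{spec.platform_id}:g{g}" for g in genes],
                values=np.power(2.0, log2x),
                sample_ids=[m.sample_id for m in samples],
                scale=SCALE_INTENSITY,
            )
        )
        annotations.append(
            GeneAnnotation(
                platform_id=spec.platform_id,
                table=pd.DataFrame(
                    {
                        "probe_id": [f"{spec.platform_id}:g{g}" for g in genes],
                        "gene_id": genes,
                        "symbol": [f"G{g}" for g in genes],
                        "chromosome": chrom.loc[genes].to_numpy(),
                    }
                ),
            )
        )
    return studies, meta, annotations, truth


def generate_codelink_raw(config: SimulationConfig) -> list[RawSpotTable]:
    """Raw spot tables (signal + background channels) for platform 0's arrays.

    A configured fraction of spots is drawn strictly below the flagging
    threshold ``B_L + k_sigma * sigma_BL`` so the flagger has known
    positives and negatives; the rest sit strictly above it with
    log-normal signal mass.
    """
    studies, meta, _, _ = generate_multiplatform_study(config)
    study = studies[0]
    rng = _rng(config, _SS_RAW)
    tables: list[RawSpotTable] = []
    n = study.n_probes if config.n_spots_raw == 0 else config.n_spots_raw
    probe_ids = study.probe_ids[:n]
    for j, array_id in enumerate(study.sample_ids):
        local_bg = np.maximum(1.0, rng.normal(200.0, 20.0, size=n))
        local_bg_sd = np.maximum(1.0, rng.normal(20.0, 3.0, size=n))
        global_bg = float(np.median(local_bg)) * rng.uniform(0.9, 1.05)
        low = rng.random(n) < config.fraction_low
        margin = config.k_sigma_raw * local_bg_sd
        signal = np.empty(n)
        # below threshold by construction
        signal[low] = local_bg[low] + margin[low] * rng.uniform(0.0, 0.95, low.sum())
        # above threshold: background + flag margin + expression intensity
        intensity = study.values[:n, j][~low]
        signal[~low] = local_bg[~low] + margin[~low] + intensity
        tables.append(
            RawSpotTable(
                array_id=array_id,
                probe_ids=list(probe_ids),
                signal=signal,
                local_bg=local_bg,
                local_bg_sd=local_bg_sd,
                global_bg=global_bg,
                flags=np.array([FLAG_OK] * n, dtype=object),
            )
        )
    return tables


def generate_annotation_and_terms(
    config: SimulationConfig,
) -> tuple[GeneAnnotation, list[TermSet]]:
    """Universe-level annotation plus GO/pathway-style term sets.

    ``n_enriched_terms`` terms are planted to overlap the planted common
    genes (``enriched_overlap`` members each); the remaining terms are
    uniform draws from the universe and so carry no signal.
    """
    truth = _plant_truth(config)
    chrom = _chromosome_assignment(config)
    universe = _universe(config)
    annotation = GeneAnnotation(
        platform_id="universe",
        table=pd.DataFrame(
            {
                "probe_id": [f"g{g}" for g in universe],
                "gene_id": universe,
                "symbol": [f"G{g}" for g in universe],
                "chromosome": chrom.loc[universe].to_numpy(),
            }
        ),
    )
    rng = _rng(config, _SS_TERMS)
    common = np.array(sorted(truth.common_up | truth.common_down), dtype=int)
    others = np.array(sorted(set(universe.tolist()) - set(common.tolist())), dtype=int)
    terms: list[TermSet] = []
    for i in range(config.n_enriched_terms):
        k = min(config.enriched_overlap, len(common))
        members = set(rng.choice(common, size=k, replace=False).tolist())
        fill = config.enriched_term_size - k
        members |= set(rng.choice(others, size=fill, replace=False).tolist())
        terms.append(
            TermSet(f"ENRICHED_{i + 1}", "planted enriched term",
                    frozenset(int(g) for g in members))
        )
    lo, hi = config.term_size_range
    for i in range(config.n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(universe, size=size, replace=False)
        terms.append(
            TermSet(f"TERM_{i + 1:03d}", "random term",
                    frozenset(int(g) for g in members))
        )
    return annotation, terms
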