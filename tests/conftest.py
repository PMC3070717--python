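"""Shared fixtures: tiny harmonized studies and call-table builders."""
from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from xplatde.harmonize import HarmonizedStudy, assign_groups
from xplatde.io_formats import CLS_CONTROL, CLS_TUMOR, SampleMeta
from xplatde.synthetic import PlatformSpec, SimulationConfig


def make_harmonized(values: np.ndarray, n_controls: int, groups: list[str],
                    gene_ids: list[int] | None = None,
                    platform: str = "p1") -> HarmonizedStudy:
    """Build a HarmonizedStudy from a matrix whose first columns are controls
    and remaining columns are tumors cycling over ``groups``."""
    values = np.asarray(values, dtype=float)
    n_genes, n_samples = values.shape
    gene_ids = gene_ids or list(range(1, n_genes + 1))
    meta = []
    sample_ids = []
    for j in range(n_samples):
        if j < n_controls:
            sid = f"C{j + 1}"
            meta.append(SampleMeta(sid, platform, CLS_CONTROL, ""))
        else:
            sid = f"T{j - n_controls + 1}"
            meta.append(
                SampleMeta(sid, platform, CLS_TUMOR,
                           groups[(j - n_controls) % len(groups)])
            )
        sample_ids.append(sid)
    return HarmonizedStudy(
        gene_ids=gene_ids,
        values=values,
        sample_ids=sample_ids,
        meta=meta,
        groups=assign_groups(meta, groups),
        platform_of={m.sample_id: m.platform_id for m in meta},
    )


def make_calls(rows: list[tuple], alpha: float = 0.05) -> pd.DataFrame:
    """Call table from (gene_id, unit, statistic, p) rows; mode intra_z."""
    from xplatde.diffexpr import call_de, _new_calls

    gene_id = [r[0] for r in rows]
    unit = [r[1] for r in rows]
    stat = [r[2] for r in rows]
    p = [r[3] for r in rows]
    return call_de(_new_calls(gene_id, unit, "intra_z", stat, p), alpha=alpha)


@pytest.fixture
def tiny_sim_config() -> SimulationConfig:
    """Two small platforms, 4 groups — fast enough for per-test generation."""
    return SimulationConfig(
        n_genes_universe=300,
        platforms=(
            PlatformSpec("pA", 1.0, 4, 8, shift=0.0, scale=1.0),
            PlatformSpec("pB", 0.9, 3, 8, shift=0.5, scale=1.1),
        ),
        groups=("g1", "g2", "g3", "g4"),
        n_common_up=10,
        n_common_down=15,
        n_group_specific=2,
        noise_sd=0.5,
        effect_common=1.5,
        seed=7,
    )
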