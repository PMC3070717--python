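"""Set-algebra commonality rules over differential-expression call tables.

Every rule here is pure set algebra: results are invariant to row order
and unit relabeling.  A gene that is unmeasured (masked p) in a unit
counts as not-DE in intersections; such genes are reported separately in
the report's provenance so strict simultaneity stays transparent.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diffexpr import DIR_DOWN, DIR_UP
from .io_formats import ValidationError

RULE_DE_ALL = "DE_in_all_units"
RULE_UP_ALL = "up_in_all"
RULE_DOWN_ALL = "down_in_all"


@dataclass
class CommonalityReport:
    rule_id: str
    gene_ids: frozenset[int]
    provenance: dict = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.gene_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"rule_id": self.rule_id, "gene_id": sorted(self.gene_ids)}
        )


def _pivot(calls: pd.DataFrame, column: str) -> pd.DataFrame:
    """gene x unit table of the given column; absent pairs become NaN."""
    return calls.pivot(index="gene_id", columns="unit", values=column)


def _alpha_of(calls: pd.DataFrame) -> float | None:
    return calls.attrs.get("alpha")


def _units(calls: pd.DataFrame) -> list:
    return sorted(calls["unit"].unique().tolist())


def _measured_everywhere(calls: pd.DataFrame) -> tuple[pd.Index, set[int]]:
    p = _pivot(calls, "p")
    measured = p.notna().all(axis=1)
    return p.index[measured], set(int(g) for g in p.index[~measured])


def intersect_de_all_units(calls: pd.DataFrame) -> CommonalityReport:
    """Genes significant (any direction) in every unit simultaneously."""
    sig = _pivot(calls, "significant").eq(True)
    hit = sig.all(axis=1)
    _, unmeasured = _measured_everywhere(calls)
    return CommonalityReport(
        rule_id=RULE_DE_ALL,
        gene_ids=frozenset(int(g) for g in sig.index[hit]),
        provenance={"units": _units(calls), "alpha": _alpha_of(calls),
                    "unmeasured": sorted(unmeasured)},
    )


def simultaneous_direction_sets(
    calls: pd.DataFrame,
) -> tuple[CommonalityReport, CommonalityReport]:
    """Genes significantly up in every unit, and down in every unit."""
    direction = _pivot(calls, "direction")
    _, unmeasured = _measured_everywhere(calls)
    prov = {"units": _units(calls), "alpha": _alpha_of(calls),
            "unmeasured": sorted(unmeasured)}
    up = direction.eq(DIR_UP).all(axis=1)
    down = direction.eq(DIR_DOWN).all(axis=1)
    return (
        CommonalityReport(RULE_UP_ALL,
                          frozenset(int(g) for g in direction.index[up]), prov),
        CommonalityReport(RULE_DOWN_ALL,
                          frozenset(int(g) for g in direction.index[down]), prov),
    )


def group_pair_combinations(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame,
    label_a: str = "A", label_b: str = "B",
) -> list[CommonalityReport]:
    """All directional combinations between two group contrasts.

    Emits common-DE (any direction), up/up, down/down, and the two
    cross-direction sets (up in one group, down in the other).
    """
    def sets(calls: pd.DataFrame) -> tuple[set[int], set[int], set[int]]:
        sig = calls[calls["significant"]]
        up = set(sig.loc[sig["direction"] == DIR_UP, "gene_id"].astype(int))
        down = set(sig.loc[sig["direction"] == DIR_DOWN, "gene_id"].astype(int))
        return up | down, up, down

    de_a, up_a, down_a = sets(calls_a)
    de_b, up_b, down_b = sets(calls_b)
    prov = {"groups": [label_a, label_b],
            "alpha": _alpha_of(calls_a) or _alpha_of(calls_b)}
    combos = [
        (f"common_{label_a}_{label_b}", de_a & de_b),
        (f"up{label_a}_up{label_b}", up_a & up_b),
        (f"down{label_a}_down{label_b}", down_a & down_b),
        (f"up{label_a}_down{label_b}", up_a & down_b),
        (f"down{label_a}_up{label_b}", down_a & up_b),
    ]
    return [CommonalityReport(rid, frozenset(g), dict(prov)) for rid, g in combos]


def combined_case_selection(
    intra: pd.DataFrame, inter: pd.DataFrame, case: str, alpha: float = 0.05
) -> CommonalityReport:
    """Genes unchanged in one per-sample mode and DE in the other.

    ``intra_unchanged_inter_DE``: p >= alpha in every intra unit AND
    significant in at least one inter unit; ``inter_unchanged_intra_DE``
    is the converse.  'Unchanged' requires the gene to be measured and
    non-significant in every unit of that mode.
    """
    if case not in ("intra_unchanged_inter_DE", "inter_unchanged_intra_DE"):
        raise ValidationError(f"unknown case {case!r}")
    units_intra = set(intra["unit"].unique())
    units_inter = set(inter["unit"].unique())
    if units_intra != units_inter:
        raise ValidationError("intra and inter call tables cover different units")
    if case == "intra_unchanged_inter_DE":
        quiet, active = intra, inter
    else:
        quiet, active = inter, intra
    p_quiet = _pivot(quiet, "p")
    unchanged = p_quiet.notna().all(axis=1) & (p_quiet >= alpha).all(axis=1)
    sig_active = _pivot(active, "significant").eq(True)
    hit_any = sig_active.any(axis=1)
    genes = set(p_quiet.index[unchanged]) & set(sig_active.index[hit_any])
    return CommonalityReport(
        rule_id=case,
        gene_ids=frozenset(int(g) for g in genes),
        provenance={"units": sorted(units_intra), "alpha": alpha},
    )


def de_incidence_ranking(calls: pd.DataFrame) -> pd.DataFrame:
    """Genes ranked by the number of units calling them DE.

    Descending by count, ties broken by gene id ascending; ``fraction``
    is count / total units.
    """
    sig = _pivot(calls, "significant").eq(True)
    n_units = sig.shape[1]
    counts = sig.sum(axis=1).astype(int)
    out = pd.DataFrame(
        {"gene_id": counts.index.astype(int), "n_units_de": counts.to_numpy()}
    )
    out["fraction"] = out["n_units_de"] / n_units
    out = out.sort_values(
        ["n_units_de", "gene_id"], ascending=[False, True], kind="stable"
    ).reset_index(drop=True)
    return out


def group_common_marker(
    group_calls: dict[str, pd.DataFrame], tolerance: int = 0
) -> CommonalityReport:
    """Genes significant in at least (n_groups - tolerance) group contrasts."""
    if len(group_calls) < 2:
        raise ValidationError("need at least two groups")
    if tolerance < 0 or tolerance >= len(group_calls):
        raise ValidationError("tolerance must lie in [0, n_groups)")
    counts: pd.Series | None = None
    for label, calls in group_calls.items():
        sig = (
            calls[calls["significant"]]
            .drop_duplicates("gene_id")
            .set_index("gene_id")["significant"]
            .astype(int)
        )
        counts = sig if counts is None else counts.add(sig, fill_value=0)
    assert counts is not None
    need = len(group_calls) - tolerance
    genes = frozenset(int(g) for g in counts.index[counts >= need])
    return CommonalityReport(
        rule_id=f"DE_in_all_groups_tol_{tolerance}",
        gene_ids=genes,
        provenance={"groups": sorted(group_calls), "tolerance": tolerance},
    )


def cross_platform_direction_sets(
    platform_calls: pd.DataFrame,
) -> tuple[CommonalityReport, CommonalityReport]:
    """Final cross-platform commonality: simultaneous direction across the
    per-platform contrasts (units = platform ids) on harmonized data."""
    up, down = simultaneous_direction_sets(platform_calls)
    up.provenance["rule"] = "intersection over platforms"
    down.provenance["rule"] = "intersection over platforms"
    return up, down
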