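"""Annotation over-representation, motif incidence and multi-pathway genes.

Over-representation uses the inclusive upper-tail hypergeometric
probability P[X >= k] for an overlap of k query genes with a term of K
genes in a universe of N, with Storey q-values over the term family.
Under-representation is not computed.

The package bundles two small published reference tables for a 17-gene
bladder-cancer common marker panel: a TF-binding-motif incidence table
(motif -> member genes, with the published per-motif incidence counts)
and pathway memberships (KEGG / Pathway Commons / Wikipathways) for four
of those genes, used by the incidence-tally and multi-pathway-selection
utilities and their tests.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .diffexpr import storey_qvalues
from .io_formats import TermSet, ValidationError, read_gmt, read_motif_tsv

MIN_TERM_SIZE = 2  # terms smaller than this after universe intersection are skipped


def hypergeometric_enrichment(
    query, terms: list[TermSet], universe, lam: float = 0.5
) -> pd.DataFrame:
    """Upper-tail hypergeometric over-representation of each term.

    Returns a DataFrame (term_id, term_name, k, K, n, N, p, q) sorted by
    p ascending; terms with fewer than two genes inside the universe are
    skipped.  The query must be a subset of the universe.
    """
    universe = set(int(g) for g in universe)
    query = set(int(g) for g in query)
    if not universe or not query:
        raise ValidationError("query and universe must be non-empty")
    if not query <= universe:
        raise ValidationError("query is not a subset of the universe")
    n, n_universe = len(query), len(universe)
    rows = []
    for t in terms:
        members = t.gene_ids & universe
        if len(members) < MIN_TERM_SIZE:
            continue
        k = len(members & query)
        rows.append(
            {
                "term_id": t.term_id,
                "term_name": t.term_name,
                "k": k,
                "K": len(members),
                "n": n,
                "N": n_universe,
                "p": float(stats.hypergeom.sf(k - 1, n_universe, len(members), n)),
            }
        )
    out = pd.DataFrame(rows, columns=["term_id", "term_name", "k", "K", "n", "N", "p"])
    if len(out):
        out["q"] = storey_qvalues(out["p"].to_numpy(), lam=lam).q
        out = out.sort_values(["p", "term_id"], kind="stable").reset_index(drop=True)
    else:
        out["q"] = []
    return out


def motif_incidence(
    motif_sets: list[TermSet],
) -> tuple[pd.Series, pd.Series, list[int]]:
    """Tally motif->gene incidence.

    Returns (per-motif gene counts, per-gene motif counts, top genes).
    The top genes are all genes attaining the maximal motif count (ties
    listed, ascending by gene id).
    """
    per_motif = pd.Series(
        {t.term_id: len(t.gene_ids) for t in motif_sets}, dtype=int, name="n_genes"
    )
    gene_counts: dict[int, int] = {}
    for t in motif_sets:
        for g in t.gene_ids:
            gene_counts[g] = gene_counts.get(g, 0) + 1
    per_gene = pd.Series(gene_counts, dtype=int, name="n_motifs").sort_index()
    if len(per_gene):
        top = sorted(per_gene.index[per_gene == per_gene.max()].tolist())
    else:
        top = []
    return per_motif, per_gene, top


def multi_pathway_gene_selection(
    pathway_sets: list[TermSet], genes, min_pathways: int = 2
) -> frozenset[int]:
    """Genes (from the supplied set) belonging to >= min_pathways pathways."""
    if min_pathways < 1:
        raise ValidationError("min_pathways must be >= 1")
    genes = set(int(g) for g in genes)
    counts: dict[int, int] = {}
    for t in pathway_sets:
        for g in t.gene_ids & genes:
            counts[g] = counts.get(g, 0) + 1
    return frozenset(g for g, c in counts.items() if c >= min_pathways)


# ---------------------------------------------------------------------------
# bundled reference tables
# ---------------------------------------------------------------------------

def _data_path(name: str):
    return resources.files("xplatde.data").joinpath(name)


def load_reference_motifs() -> tuple[list[TermSet], pd.Series]:
    """The published TFBM incidence table for the 17-gene marker panel."""
    with resources.as_file(_data_path("bladder17_tfbm.tsv")) as p:
        return read_motif_tsv(p)


def load_reference_pathways() -> list[TermSet]:
    """Published pathway memberships for the marker panel's genes."""
    with resources.as_file(_data_path("bladder17_pathways.gmt")) as p:
        return read_gmt(p)


def load_reference_symbols() -> pd.Series:
    """NCBI Gene ID -> symbol for the 17-gene marker panel."""
    with resources.as_file(_data_path("bladder17_genes.tsv")) as p:
        df = pd.read_csv(p, sep="\t", dtype={"gene_id": int, "symbol": str})
    return df.set_index("gene_id")["symbol"]
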