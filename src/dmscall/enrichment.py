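"""Hypergeometric gene-set enrichment of differentially modified genes.

For each modification code, a gene is a "success" if it carries at least
one differentially modified site.  Enrichment of a gene set (e.g. type 2
diabetes effector genes) is then the upper-tail hypergeometric probability
of drawing at least the observed overlap when ``n_hits`` genes are drawn
without replacement from a universe of ``n_universe`` genes of which
``n_set_in_universe`` belong to the set.  The universe is the set of genes
with at least one site that entered testing for that modification.

The tail probability is computed with exact integer combinatorics
(``math.comb``), so small-universe results agree with exhaustive
enumeration to the last bit.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from math import comb

import pandas as pd

from .meta_infer import bh_adjust

logger = logging.getLogger(__name__)


def hypergeom_test(
    n_overlap: int, n_hits: int, n_set_in_universe: int, n_universe: int
) -> float:
    """Upper-tail P(X >= n_overlap), X ~ Hypergeom(n_universe,
    n_set_in_universe, n_hits).

    The observed overlap is included in the tail (P[X >= k]), the standard
    convention for over-representation of successes.
    """
    if not 0 <= n_hits <= n_universe:
        raise ValueError("n_hits must lie in [0, n_universe]")
    if not 0 <= n_set_in_universe <= n_universe:
        raise ValueError("n_set_in_universe must lie in [0, n_universe]")
    if not 0 <= n_overlap <= min(n_hits, n_set_in_universe):
        raise ValueError(
            "n_overlap must lie in [0, min(n_hits, n_set_in_universe)]"
        )
    total = comb(n_universe, n_hits)
    upper = min(n_hits, n_set_in_universe)
    acc = 0
    for k in range(n_overlap, upper + 1):
        acc += comb(n_set_in_universe, k) * comb(
            n_universe - n_set_in_universe, n_hits - k
        )
    return float(Fraction(acc, total))


def genes_with_dms(
    dms: pd.DataFrame, gene_map: pd.DataFrame
) -> tuple[dict[str, set[str]], dict[str, set[str]], set[str]]:
    """Map tested/DMS sites to genes through a transcript->gene map.

    Returns ``(hits, universe, unmapped)``: per-mod sets of genes with at
    least one DMS, per-mod sets of genes with at least one tested site, and
    the references that had no entry in the map (excluded and logged).
    """
    if gene_map.empty:
        raise ValueError("empty gene map")
    tx2gene = dict(zip(gene_map["transcript_id"], gene_map["gene_id"]))
    genes = dms["reference"].map(tx2gene)
    unmapped = set(dms.loc[genes.isna(), "reference"])
    if unmapped:
        logger.warning(
            "%d references missing from gene map (excluded): %s%s",
            len(unmapped),
            sorted(unmapped)[:5],
            "..." if len(unmapped) > 5 else "",
        )
    mapped = dms.assign(gene_id=genes).dropna(subset=["gene_id"])
    hits: dict[str, set[str]] = {}
    universe: dict[str, set[str]] = {}
    for mod, sub in mapped.groupby("mod_code"):
        universe[str(mod)] = set(sub["gene_id"])
        hits[str(mod)] = set(sub.loc[sub["is_dms"], "gene_id"])
    return hits, universe, unmapped


def read_gene_sets(path) -> pd.DataFrame:
    """Read a gene-set TSV with columns (set_name, gene_id)."""
    gs = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("set_name", "gene_id"):
        if col not in gs.columns:
            raise ValueError(f"gene-set file missing column {col!r}")
    return gs


def enrich_gene_sets(
    dms: pd.DataFrame, gene_map: pd.DataFrame, gene_sets: pd.DataFrame
) -> pd.DataFrame:
    """Test every (modification, gene set) pair for over-representation.

    BH correction is applied jointly across all tested pairs.  Returns one
    row per pair with counts, p and q.
    """
    hits, universe, _ = genes_with_dms(dms, gene_map)
    rows = []
    for set_name, sub in gene_sets.groupby("set_name"):
        members = set(sub["gene_id"])
        for mod in sorted(universe):
            uni = universe[mod]
            hit = hits.get(mod, set())
            set_in_uni = members & uni
            overlap = hit & set_in_uni
            p = hypergeom_test(
                len(overlap), len(hit), len(set_in_uni), len(uni)
            )
            rows.append(
                {
                    "mod_code": mod,
                    "set_name": set_name,
                    "n_universe": len(uni),
                    "n_set_in_universe": len(set_in_uni),
                    "n_hits": len(hit),
                    "n_overlap": len(overlap),
                    "p": p,
                }
            )
    result = pd.DataFrame(rows)
    if not result.empty:
        result["q"] = bh_adjust(result["p"].to_numpy())
    return result
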