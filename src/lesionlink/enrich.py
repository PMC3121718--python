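"""Gene-set overrepresentation analysis for DE and anchored gene lists.

Hypergeometric (one-sided Fisher) tail probabilities against GMT term
collections, reported alongside the conservative EASE variant (the
jackknifed Fisher p-value with the overlap reduced by one) and BH-adjusted
across terms.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from scipy import stats

from .diffexpr import benjamini_hochberg

__all__ = ["read_gmt", "write_gmt", "hypergeom_enrich", "rank_terms", "GeneSetEnrichment"]


def read_gmt(path) -> dict:
    """Parse a GMT file: term <tab> description <tab> gene1 <tab> gene2 ..."""
    sets = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs term, "
                                 "description and at least one gene")
            sets[parts[0]] = [g for g in parts[2:] if g]
    return sets


def write_gmt(sets: dict, path, description: str = "na") -> None:
    with open(path, "w") as fh:
        for term, genes in sets.items():
            fh.write("\t".join([term, description, *genes]) + "\n")


def hypergeom_enrich(gene_list, term_sets: dict, universe) -> pd.DataFrame:
    """Overrepresentation of each term in ``gene_list``.

    fisher_p = P(X >= k) with X ~ Hypergeometric(N, K, n); ease_p is the
    same tail with the observed overlap reduced by one (floored at zero).
    Terms are intersected with the universe; the gene list must be a
    subset of the universe.
    """
    universe = set(universe)
    genes = set(gene_list)
    if not universe:
        raise ValueError("empty universe")
    if not genes:
        raise ValueError("empty gene list")
    if not genes <= universe:
        raise ValueError("gene list is not a subset of the universe")
    N, n = len(universe), len(genes)
    rows = []
    for term, members in term_sets.items():
        members = set(members) & universe
        K = len(members)
        overlap = sorted(genes & members)
        k = len(overlap)
        fisher_p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        ease_p = float(stats.hypergeom.sf(k - 2, N, K, n)) if k > 1 else 1.0
        rows.append({"term_id": term, "term_size": K, "list_size": n,
                     "overlap": k, "universe_size": N,
                     "fisher_p": min(fisher_p, 1.0), "ease_p": min(ease_p, 1.0),
                     "genes": ",".join(overlap)})
    out = pd.DataFrame(rows)
    if len(out):
        out["bh_q"] = benjamini_hochberg(out["ease_p"].to_numpy())
    return out


def rank_terms(results: pd.DataFrame, top_m: int | None = None) -> pd.DataFrame:
    """Order terms by ascending EASE p, ties broken by larger overlap then id."""
    if results.empty:
        raise ValueError("no enrichment results to rank")
    out = results.sort_values(
        by=["ease_p", "overlap", "term_id"],
        ascending=[True, False, True], kind="stable").reset_index(drop=True)
    if top_m is not None:
        out = out.head(top_m)
    return out


@dataclass
class GeneSetEnrichment:
    """Estimator computing term overrepresentation for one gene list.

    The universe defaults to all genes represented on the expression
    matrix after filtering; pass it explicitly to override.
    """

    top_m: int | None = None

    def get_params(self, deep: bool = True) -> dict:
        return {"top_m": self.top_m}

    def set_params(self, **params) -> "GeneSetEnrichment":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, gene_list, term_sets: dict, universe) -> "GeneSetEnrichment":
        res = hypergeom_enrich(gene_list, term_sets, universe)
        self.results_ = rank_terms(res, self.top_m) if len(res) else res
        return self
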