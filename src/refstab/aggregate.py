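"""Comprehensive ranking: geometric mean of the four per-method ranks.

Each candidate gene's final stability ranking is the geometric mean of
its dense ranks under the comparative delta-Ct, geNorm, NormFinder and
BestKeeper methods — the aggregation popularised by the RefFinder
platform. Final ranks follow ascending geometric mean; exact ties break
by the delta-Ct statistic, then by gene id.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from refstab.stability import StabilityResult

__all__ = ["ComprehensiveRanking", "comprehensive_ranking", "rank_table", "METHOD_ORDER"]

METHOD_ORDER = ("delta_ct", "genorm", "normfinder", "bestkeeper")


@dataclass
class ComprehensiveRanking:
    """Per-gene method ranks, their geometric mean, and the final ordering."""

    per_gene: dict[str, dict]  # gene -> {method_ranks, geomean, final_rank}

    def ordering(self) -> list[str]:
        """Gene ids from most to least stable."""
        return sorted(self.per_gene, key=lambda g: self.per_gene[g]["final_rank"])

    def geomean(self, gene: str, decimals: int | None = 2) -> float:
        gm = self.per_gene[gene]["geomean"]
        return round(gm, decimals) if decimals is not None else gm

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.ordering():
            entry = self.per_gene[g]
            row = {"gene": g, "geomean": entry["geomean"], "final_rank": entry["final_rank"]}
            for m in METHOD_ORDER:
                row[f"rank_{m}"] = entry["method_ranks"][m]
            rows.append(row)
        return pd.DataFrame(rows)


def comprehensive_ranking(results: Sequence[StabilityResult]) -> ComprehensiveRanking:
    """Aggregate exactly four method results into the comprehensive ranking.

    All four methods must be present with identical gene sets. The
    geometric mean is computed at full precision (rounding to two
    decimals is applied only when reporting); final-rank ties break by
    the delta-Ct statistic, then lexicographic gene id.
    """
    by_method = {r.method: r for r in results}
    missing = set(METHOD_ORDER) - set(by_method)
    if missing or len(results) != 4:
        raise ValueError(
            f"comprehensive ranking needs exactly the four methods {METHOD_ORDER}; "
            f"missing: {sorted(missing)}"
        )
    gene_sets = [frozenset(r.per_gene) for r in results]
    if len(set(gene_sets)) != 1:
        raise ValueError("gene sets differ across methods")
    genes = sorted(gene_sets[0])

    per_gene: dict[str, dict] = {}
    for g in genes:
        ranks = {m: by_method[m].ranks[g] for m in METHOD_ORDER}
        vec = np.array([ranks[m] for m in METHOD_ORDER], dtype=float)
        per_gene[g] = {
            "method_ranks": ranks,
            "geomean": float(np.exp(np.log(vec).mean())),
        }

    delta_stat = by_method["delta_ct"].per_gene
    order = sorted(genes, key=lambda g: (per_gene[g]["geomean"], delta_stat[g], g))
    for i, g in enumerate(order, start=1):
        per_gene[g]["final_rank"] = i
    return ComprehensiveRanking(per_gene=per_gene)


def rank_table(results: Sequence[StabilityResult]) -> pd.DataFrame:
    """Render the full stability report: one row per gene, the comprehensive
    geomean/rank first, then (statistic, rank) per method.

    Geomeans are reported rounded to two decimals; per-method statistics
    keep full precision.
    """
    comp = comprehensive_ranking(results)
    by_method = {r.method: r for r in results}
    rows = []
    for g in comp.ordering():
        entry = comp.per_gene[g]
        row: dict = {
            "gene": g,
            "comprehensive_geomean": round(entry["geomean"], 2),
            "comprehensive_rank": entry["final_rank"],
        }
        for m in METHOD_ORDER:
            row[f"{m}_statistic"] = by_method[m].per_gene[g]
            row[f"{m}_rank"] = by_method[m].ranks[g]
        rows.append(row)
    return pd.DataFrame(rows)
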