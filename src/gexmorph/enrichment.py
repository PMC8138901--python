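"""Fisher's-exact over-representation analysis of ranked gene tails.

The top (or bottom) 2.5% of genes by spatial correlation are tested for
over-representation in each catalog category against an explicit background
(the full tested gene universe). For a category with K background members,
a selection of n genes containing k members has one-sided p

    p = sum_{j >= k} C(K, j) C(N - K, n - j) / C(N, n)

(the hypergeometric upper tail), and enrichment factor (k/n) / (K/N).
Q values are Benjamini-Hochberg over all tested categories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from ._validate import ValidationError, require
from .association import bh_fdr


@dataclass(frozen=True)
class GeneSet:
    id: str
    name: str
    members: frozenset[str]


@dataclass
class GeneSetCatalog:
    """An ordered collection of named gene sets (GMT-file semantics)."""

    sets: list[GeneSet]
    source: str = ""
    enriched_ids: list[str] = field(default_factory=list)  # synthetic truth

    def validate(self) -> "GeneSetCatalog":
        ids = [s.id for s in self.sets]
        require(len(ids) == len(set(ids)), "duplicate category ids in catalog")
        for s in self.sets:
            require(len(s.members) > 0, f"category {s.id!r} has no members")
        return self

    def __len__(self) -> int:
        return len(self.sets)


def select_top_genes(association: pd.DataFrame, fraction: float = 0.025,
                     tail: str = "positive") -> list[str]:
    """The floor(fraction * n) most positively (or negatively) ranked genes.

    Ties at the cutoff boundary are broken by lexicographic gene id so the
    selection is deterministic.
    """
    require(0.0 < fraction <= 1.0, f"fraction must lie in (0, 1], got {fraction}")
    require(tail in ("positive", "negative"),
            f"tail must be 'positive' or 'negative', got {tail!r}")
    n_select = int(np.floor(fraction * len(association)))
    if n_select == 0:
        raise ValidationError(
            f"fraction {fraction} of {len(association)} genes selects nothing")
    tmp = association.reset_index()
    gene_col = tmp.columns[0]       # the gene-id index column
    ordered = tmp.sort_values(["rho", gene_col],
                              ascending=[tail == "negative", True],
                              kind="stable")
    return list(ordered[gene_col].iloc[:n_select])


def fisher_enrichment(selected, catalog: GeneSetCatalog, background, *,
                      min_category: int = 3) -> pd.DataFrame:
    """One-sided over-representation test per category, BH-corrected.

    Categories are intersected with the background before testing;
    categories with fewer than ``min_category`` background members (or none)
    are excluded. Results are sorted by p.
    """
    selected = set(selected)
    background = set(background)
    offenders = selected - background
    if offenders:
        raise ValidationError(
            f"selected genes outside the background: {sorted(offenders)[:10]}")
    catalog.validate()
    N = len(background)
    n = len(selected)

    rows = []
    for gs in catalog.sets:
        members = gs.members & background
        K = len(members)
        if K == 0 or K < min_category:
            continue
        k = len(members & selected)
        p = float(hypergeom.sf(k - 1, N, K, n))
        factor = (k / n) / (K / N) if n > 0 else np.nan
        rows.append((gs.id, gs.name, k, n, K, N, factor, p))
    table = pd.DataFrame(rows, columns=["category", "name", "k", "n", "K",
                                        "N", "factor", "p"])
    if len(table):
        table["q"] = bh_fdr(table["p"].to_numpy())
        table = table.sort_values(["p", "category"], kind="stable"
                                  ).reset_index(drop=True)
    else:
        table["q"] = pd.Series(dtype=float)
    return table
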