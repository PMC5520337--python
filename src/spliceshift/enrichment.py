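"""Gene-set over-representation analysis of changed genes.

One-sided hypergeometric test: with a universe of N genes assayed on the
arrays, K of which belong to a pathway, and n changed genes, the p-value
for observing k changed pathway genes is P(X >= k) under sampling without
replacement.  The universe is the gene-level pool actually represented on
the arrays (a gene carrying two events counts once), not the genome.
P-values are Benjamini–Hochberg adjusted across the tested sets.

Gene sets are read from GMT files (set name, description, gene symbols,
tab-separated), the de facto interchange format for pathway collections.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

__all__ = ["GeneSetCollection", "read_gmt", "test_overrepresentation", "ENRICHMENT_COLUMNS"]

logger = logging.getLogger(__name__)

ENRICHMENT_COLUMNS = ["set_name", "k", "K", "n", "N", "p_value", "p_adjusted"]


@dataclass
class GeneSetCollection:
    """Ordered, named sets of (uppercased, deduplicated) gene symbols."""

    sets: dict[str, list[str]]
    source: str = ""

    def __post_init__(self) -> None:
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name <TAB> description <TAB> gene [<TAB> gene ...]."""
    path = Path(path)
    sets: dict[str, list[str]] = {}
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3 or not any(g.strip() for g in fields[2:]):
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and >=1 gene")
            name = fields[0]
            seen: dict[str, None] = {}
            for g in fields[2:]:
                g = g.strip().upper()
                if g:
                    seen[g] = None
            sets[name] = list(seen)
    return GeneSetCollection(sets=sets, source=str(path))


def test_overrepresentation(
    changed_genes: Iterable[str],
    universe_genes: Iterable[str],
    collection: GeneSetCollection,
) -> pd.DataFrame:
    """Hypergeometric over-representation of changed genes per set.

    Sets are intersected with the universe before testing; sets disjoint
    from the universe are skipped (logged).  Returns a DataFrame following
    :data:`ENRICHMENT_COLUMNS`, sorted by p-value.
    """
    universe = {g.upper() for g in universe_genes}
    changed = {g.upper() for g in changed_genes}
    if len(universe) < 2:
        raise ValueError("universe must contain >= 2 genes")
    offenders = sorted(changed - universe)
    if offenders:
        raise ValueError(f"changed genes not in universe: {', '.join(offenders)}")
    N, n = len(universe), len(changed)
    rows = []
    for name, genes in collection.sets.items():
        in_universe = universe.intersection(genes)
        if not in_universe:
            logger.info("gene set %r shares no genes with the universe; skipped", name)
            continue
        K = len(in_universe)
        k = len(changed.intersection(in_universe))
        p = float(hypergeom.sf(k - 1, N, K, n))  # upper tail P(X >= k)
        rows.append({"set_name": name, "k": k, "K": K, "n": n, "N": N, "p_value": p})
    result = pd.DataFrame(rows, columns=ENRICHMENT_COLUMNS[:-1])
    if len(result):
        result["p_adjusted"] = multipletests(result["p_value"], method="fdr_bh")[1]
        result = result.sort_values("p_value", kind="stable").reset_index(drop=True)
    else:
        result["p_adjusted"] = pd.Series(dtype=float)
    return result
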