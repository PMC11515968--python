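"""Over-representation analysis of target-gene lists against annotation sets.

Given a query gene list (e.g., predicted targets of differential miRNAs)
and a collection of annotation sets over a gene universe, each set is scored
with the hypergeometric upper tail P(X >= overlap), fold enrichment
(query overlap rate over universe set rate), and Benjamini-Hochberg FDR
across sets (significant at FDR < 0.05).

miRNA->target interactions are consumed as two-column files; when several
prediction databases are given, only interactions present in all of them
are kept (the consensus-intersection rule).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)


@dataclass
class GeneSetCollection:
    """Named annotation sets over a common gene universe."""

    sets: dict[str, set[str]]
    universe: set[str]

    def __post_init__(self):
        for name, genes in self.sets.items():
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            extra = genes - self.universe
            if extra:
                raise ValueError(
                    f"gene set {name!r} has genes outside the universe: {sorted(extra)[:5]}"
                )


def read_gmt(path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Read a GMT file (name <tab> description <tab> genes...).

    Without an explicit universe, the union of all sets is used.
    """
    sets: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise ValueError(f"malformed GMT line: {line!r}")
        sets[fields[0]] = {g for g in fields[2:] if g}
    uni = set(universe) if universe is not None else set().union(*sets.values())
    return GeneSetCollection(sets=sets, universe=uni)


def ora(
    query: Iterable[str],
    collection: GeneSetCollection,
    fdr_threshold: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each annotation set.

    Query genes outside the universe are dropped with a warning. Returns a
    table sorted by p with columns overlap, set_size, fold_enrichment, p,
    fdr, significant.
    """
    q = set(query)
    outside = q - collection.universe
    if outside:
        logger.warning("%d query genes outside the universe dropped", len(outside))
        q -= outside
    if not q:
        raise ValueError("query is empty after restricting to the universe")
    M = len(collection.universe)
    N = len(q)
    rows = []
    for name, genes in collection.sets.items():
        K = len(genes)
        k = len(q & genes)
        # upper tail P(X >= k) for overlap under random draws of N from M
        p = float(stats.hypergeom.sf(k - 1, M, K, N))
        fold = (k / N) / (K / M)
        rows.append(
            {"set": name, "overlap": k, "set_size": K, "fold_enrichment": fold, "p": p}
        )
    out = pd.DataFrame(rows).set_index("set")
    out["fdr"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["fdr"] < fdr_threshold
    return out.sort_values("p")


def read_interactions(path) -> set[tuple[str, str]]:
    """Read a two-column (miRNA, gene) interaction TSV; a header is optional."""
    pairs: set[tuple[str, str]] = set()
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 2:
            raise ValueError(f"{path}:{i + 1}: expected two tab-separated columns")
        if i == 0 and fields[0].lower() in ("mirna", "mir", "microrna"):
            continue
        pairs.add((fields[0], fields[1]))
    return pairs


def intersect_interactions(paths: Sequence) -> set[tuple[str, str]]:
    """Consensus interactions: pairs present in every per-database file."""
    if not paths:
        raise ValueError("no interaction files given")
    result: set[tuple[str, str]] | None = None
    for p in paths:
        pairs = read_interactions(p)
        result = pairs if result is None else result & pairs
    return result or set()


def targets_of(mirnas: Iterable[str], interactions: Iterable[tuple[str, str]]) -> set[str]:
    """Genes targeted by any of the given miRNAs in the interaction set."""
    wanted = set(mirnas)
    return {gene for mir, gene in interactions if mir in wanted}
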