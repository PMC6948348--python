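"""Pathway over-representation analysis with false-discovery-rate control.

A query set of protein targets is tested against a gene-set collection
(KEGG-style pathways in GMT format). For each pathway with at least one hit
the right-tail hypergeometric probability

    P(X >= k),  X ~ Hypergeometric(N, K, n)

is computed, where N is the background-universe size, K the pathway size,
n the query size and k the observed overlap — the one-sided Fisher exact
test of the 2x2 overlap table. P-values across all tested pathways are then
adjusted by the Benjamini-Hochberg step-up procedure.

The tail probability is evaluated in exact big-integer rational arithmetic
(binomial coefficients over Python ints), so it is correct to the last
floating-point digit for every feasible input rather than to the accuracy of
an asymptotic or log-space approximation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from math import comb
from typing import Iterable, Sequence

import numpy as np
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

__all__ = [
    "GeneSet",
    "EnrichmentResult",
    "hypergeom_right_tail",
    "bh_fdr",
    "enrich",
    "read_gmt",
    "write_gmt",
    "results_to_frame",
]


@dataclass(frozen=True)
class GeneSet:
    """One pathway: KEGG-style id (e.g. ``hsa05200``), display name, member ids."""

    set_id: str
    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"{self.set_id}: gene set must be non-empty")


@dataclass(frozen=True)
class EnrichmentResult:
    """Per-pathway over-representation statistics.

    ``hits`` (k) is the overlap between query and pathway — the pathway's
    degree in the target-pathway network; ``fdr`` is the BH-adjusted p-value
    across all pathways tested in the same call.
    """

    set_id: str
    name: str
    hits: int
    set_size: int
    query_size: int
    background_size: int
    p_value: float
    fdr: float
    hit_list: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.hits != len(self.hit_list):
            raise ValueError(f"{self.set_id}: hits != len(hit_list)")


def hypergeom_right_tail(k: int, K: int, n: int, N: int) -> float:
    """Exact P(X >= k) for X ~ Hypergeometric(N, K, n).

    Drawing n items from an urn of N containing K marked items, the
    probability of seeing k or more marked. Computed as an exact integer
    ratio  sum_{j>=k} C(K,j) C(N-K,n-j) / C(N,n)  and rounded once to float.

    Parameters follow the enrichment convention: k hits, K pathway size,
    n query size, N background size.
    """
    for name, v in (("k", k), ("K", K), ("n", n), ("N", N)):
        if int(v) != v:
            raise ValueError(f"{name} must be an integer, got {v!r}")
    k, K, n, N = int(k), int(K), int(n), int(N)
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"infeasible counts: K={K}, n={n}, N={N}")
    if not (0 <= k <= min(K, n)):
        raise ValueError(f"infeasible overlap k={k} for K={K}, n={n}")
    numer = sum(comb(K, j) * comb(N - K, n - j) for j in range(k, min(K, n) + 1))
    return numer / comb(N, n)


def bh_fdr(p_values: Sequence[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjustment, returned in input order.

    q(i) = min_{j >= i} p(j) * m / j over the ascending-sorted p-values,
    clipped at 1. Each p must lie in (0, 1] (a p-value of exactly 0 is not
    attainable from a valid test).
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("p_values must be non-empty")
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return [float(v) for v in q]


def enrich(
    query: Iterable[str],
    collection: Sequence[GeneSet],
    background: Iterable[str] | str = "union",
    strict: bool = False,
) -> list[EnrichmentResult]:
    """Test a target set for over-representation in each gene set.

    The background universe defaults to the union of all collection members
    (``"union"``); an explicit id collection may be passed instead. Query ids
    absent from the background are dropped with a logged count (``strict``
    raises instead), matching how enrichment tools restrict the query to the
    annotated universe. Only sets overlapping the query are tested, and the
    BH correction spans exactly those tested sets. Results are sorted by
    ascending p-value, ties broken by set_id.
    """
    if not collection:
        raise ValueError("gene-set collection is empty")
    query = set(query)
    if not query:
        raise ValueError("query is empty")
    if isinstance(background, str):
        if background != "union":
            raise ValueError("background must be an id collection or 'union'")
        universe = frozenset().union(*(gs.members for gs in collection))
        logger.info("background = union of gene-set members (%d ids)", len(universe))
    else:
        universe = frozenset(background)
        outside = frozenset().union(*(gs.members for gs in collection)) - universe
        if outside:
            logger.warning(
                "%d gene-set member ids fall outside the explicit background", len(outside)
            )
    dropped = query - universe
    if dropped:
        if strict:
            raise ValueError(f"query ids absent from background: {sorted(dropped)}")
        logger.info("dropped %d query ids absent from background", len(dropped))
    query &= universe
    if not query:
        raise ValueError("query is empty after background restriction")

    N, n = len(universe), len(query)
    tested: list[tuple[GeneSet, tuple[str, ...], float]] = []
    for gs in collection:
        members = gs.members & universe
        hit_list = tuple(sorted(query & members))
        if not hit_list:
            continue
        p = hypergeom_right_tail(len(hit_list), len(members), n, N)
        tested.append((gs, hit_list, p))
    if not tested:
        raise ValueError("query overlaps no gene set; nothing to test")
    qvals = bh_fdr([p for _, _, p in tested])
    results = [
        EnrichmentResult(
            set_id=gs.set_id,
            name=gs.name,
            hits=len(hit_list),
            set_size=len(gs.members & universe),
            query_size=n,
            background_size=N,
            p_value=p,
            fdr=q,
            hit_list=hit_list,
        )
        for (gs, hit_list, p), q in zip(tested, qvals)
    ]
    return sorted(results, key=lambda r: (r.p_value, r.set_id))


# ---------------------------------------------------------------------------
# GMT and result-table I/O
# ---------------------------------------------------------------------------

def read_gmt(path) -> list[GeneSet]:
    """Read a gene-set collection in GMT format (id TAB description TAB members...)."""
    sets = []
    seen = set()
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs id, description, >=1 member")
            set_id, name, members = parts[0], parts[1], parts[2:]
            if set_id in seen:
                raise ValueError(f"{path}:{ln}: duplicate set id {set_id}")
            seen.add(set_id)
            sets.append(GeneSet(set_id, name, frozenset(m for m in members if m)))
    return sets


def write_gmt(sets: Iterable[GeneSet], path) -> None:
    with open(path, "w") as fh:
        for gs in sets:
            fh.write("\t".join([gs.set_id, gs.name, *sorted(gs.members)]) + "\n")


def results_to_frame(results: Sequence[EnrichmentResult]):
    """Enrichment results as a DataFrame (hit lists semicolon-joined)."""
    import pandas as pd

    return pd.DataFrame(
        {
            "set_id": [r.set_id for r in results],
            "name": [r.name for r in results],
            "hits": [r.hits for r in results],
            "set_size": [r.set_size for r in results],
            "query_size": [r.query_size for r in results],
            "background_size": [r.background_size for r in results],
            "p_value": [r.p_value for r in results],
            "fdr": [r.fdr for r in results],
            "hit_list": [";".join(r.hit_list) for r in results],
        }
    )
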