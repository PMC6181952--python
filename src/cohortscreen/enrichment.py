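"""Hypergeometric over-representation analysis against gene-set
collections (GMT files), with Benjamini-Hochberg correction across sets.

For a universe of N genes containing a set of K and a query of n, the
enrichment p-value is the upper tail P(X >= k) of the hypergeometric
distribution for the observed overlap k. Query genes outside the universe
are dropped (with a logged count), and duplicate query genes are ignored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .errors import DomainError, FormatError
from .perturbation_de import bh_adjust

log = logging.getLogger(__name__)


@dataclass
class GeneSet:
    set_id: str
    category_label: str
    members: frozenset

    def __post_init__(self) -> None:
        members = frozenset(str(g).strip().upper() for g in self.members)
        if not members:
            raise FormatError(f"gene set {self.set_id!r} has no members")
        object.__setattr__(self, "members", members)


def read_gmt(path) -> list[GeneSet]:
    """GMT format: one set per line — set_id <tab> description <tab>
    members..."""
    sets = []
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise FormatError(f"{path}:{i}: GMT line needs id, description, members")
        sets.append(GeneSet(fields[0], fields[1], frozenset(fields[2:]) - {""}))
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return sets


def hypergeometric_upper_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N population, K successes,
    n draws); computed via the stable log-space survival function.
    P(X >= 0) is exactly 1."""
    if not (0 <= k <= min(K, n) and 0 <= K <= N and 0 <= n <= N):
        raise DomainError(
            f"inconsistent counts: k={k}, K={K}, n={n}, N={N}"
        )
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrich(
    query: Iterable[str],
    sets: Sequence[GeneSet],
    universe: Iterable[str],
) -> pd.DataFrame:
    """Over-representation of ``query`` in each gene set, restricted to
    ``universe``; one row per set with K >= 1 in the universe, BH-adjusted
    across all tested sets, sorted by adjusted p ascending.

    Columns: set_id, category_label, k, K, n, N, p_value, adj_p.
    An empty effective query returns an empty frame with a warning.
    """
    uni = {str(g).strip().upper() for g in universe}
    if not uni:
        raise DomainError("empty universe")
    q_all = [str(g).strip().upper() for g in query]
    q = set(q_all) & uni
    dropped = len(set(q_all)) - len(q)
    if dropped:
        log.info("%d query genes outside the universe dropped", dropped)
    if not q:
        warnings.warn("query empty after intersecting with the universe")
        return pd.DataFrame(columns=["set_id", "category_label", "k", "K", "n",
                                     "N", "p_value", "adj_p"])
    N, n = len(uni), len(q)
    rows = []
    for gs in sets:
        members = gs.members & uni
        if not members:
            continue
        K = len(members)
        k = len(members & q)
        rows.append({
            "set_id": gs.set_id,
            "category_label": gs.category_label,
            "k": k, "K": K, "n": n, "N": N,
            "p_value": hypergeometric_upper_tail(k, K, n, N),
        })
    out = pd.DataFrame(rows)
    if out.empty:
        warnings.warn("no gene set overlaps the universe")
        return pd.DataFrame(columns=["set_id", "category_label", "k", "K", "n",
                                     "N", "p_value", "adj_p"])
    out["adj_p"] = bh_adjust(out["p_value"].to_numpy())
    return out.sort_values(["adj_p", "p_value", "set_id"]).reset_index(drop=True)
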