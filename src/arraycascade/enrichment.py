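"""Gene-set overrepresentation and upstream-regulator direction analysis.

Overrepresentation uses the one-tailed hypergeometric test per gene set
and the conservative EASE variant (one overlap member removed before
computing the tail), the statistic popularized by the DAVID annotation
tool. Related sets are grouped into annotation clusters by greedy overlap
clustering; each cluster's enrichment score is the mean of -log10(EASE p)
over its member sets, so a score of 2 means the typical member is
enriched at p = 0.01.

The upstream-regulator score is a directional consistency statistic over
a signed regulator -> target network: with N usable edges (target
significantly regulated, expected sign known),

    z = sum_i expected_sign_i * observed_sign_i / sqrt(N)

Regulators with z >= 2 are called activated and z <= -2 inhibited. The
statistic is deliberately unweighted; it captures the direction logic of
commercial causal-network tools without their proprietary edge weights,
so published z-values from those tools are not numerically comparable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError
from .io import GeneSetCollection, RegulatorNetwork
from .diffexp import bh_fdr

P_FLOOR = 1e-300


def _norm(symbol: str) -> str:
    return symbol.strip().upper()


def hypergeom_tail(n_hits: int, n_universe: int, n_set: int, n_query: int) -> float:
    """P(X >= n_hits) for X ~ Hypergeom(universe, set, query draws)."""
    if n_hits <= 0:
        return 1.0
    return float(stats.hypergeom.sf(n_hits - 1, n_universe, n_set, n_query))


def ease_p(n_hits: int, n_set: int, n_query: int, n_universe: int) -> float:
    """EASE score: hypergeometric tail with one overlap member jackknifed."""
    return hypergeom_tail(max(n_hits - 1, 0), n_universe, n_set, n_query)


def fisher_enrich(
    query: list[str], sets: GeneSetCollection, universe: list[str]
) -> pd.DataFrame:
    """Per-set overrepresentation table for a query gene list.

    Symbols are case-normalized; sets are intersected with the universe and
    the query must be a subset of the universe. Columns: category, n_hits,
    n_set, n_query, n_universe, p_fisher, p_ease, q (BH across sets).
    """
    uni = {_norm(g) for g in universe}
    qry = {_norm(g) for g in query}
    if not uni:
        raise DataError("empty universe")
    if not qry:
        raise DataError("empty query")
    extra = qry - uni
    if extra:
        raise DataError(f"query genes outside the universe: {sorted(extra)[:5]}")

    rows = []
    for name, gs in sets.sets.items():
        members = {_norm(m) for m in gs.members} & uni
        if not members:
            continue
        hits = len(members & qry)
        p_f = hypergeom_tail(hits, len(uni), len(members), len(qry))
        p_e = ease_p(hits, len(members), len(qry), len(uni))
        rows.append(
            {
                "set": name,
                "category": gs.category,
                "n_hits": hits,
                "n_set": len(members),
                "n_query": len(qry),
                "n_universe": len(uni),
                "p_fisher": p_f,
                "p_ease": p_e,
            }
        )
    table = pd.DataFrame(rows).set_index("set") if rows else pd.DataFrame(
        columns=["category", "n_hits", "n_set", "n_query", "n_universe",
                 "p_fisher", "p_ease"]
    )
    if len(table):
        table["q"] = bh_fdr(table["p_fisher"].to_numpy())
    else:
        table["q"] = []
    return table


@dataclass
class AnnotationCluster:
    """A group of related gene sets with a joint enrichment score."""

    name: str
    members: list[str]
    score: float


def cluster_score(p_values: list[float]) -> float:
    """Mean -log10(p) over a cluster's member sets (p floored at 1e-300)."""
    if not p_values:
        raise DataError("cluster without members")
    ps = np.asarray(p_values, dtype=float)
    if np.any(ps <= 0):
        raise DataError("non-positive p-value in cluster; floor upstream")
    return float(np.mean(-np.log10(np.maximum(ps, P_FLOOR))))


def annotation_clusters(
    enrich: pd.DataFrame,
    sets: GeneSetCollection,
    query: list[str],
    jaccard_min: float = 0.5,
) -> list[AnnotationCluster]:
    """Greedy clustering of enriched sets by query-restricted overlap.

    Sets are visited in order of increasing EASE p; each unassigned set
    seeds a cluster and absorbs every other unassigned set whose Jaccard
    similarity (on memberships restricted to the query) is >= jaccard_min.
    """
    qry = {_norm(g) for g in query}
    membership = {
        name: ({_norm(m) for m in sets.sets[name].members} & qry)
        for name in enrich.index
        if name in sets.sets
    }
    order = enrich.sort_values("p_ease").index
    assigned: set[str] = set()
    clusters: list[AnnotationCluster] = []
    for seed in order:
        if seed in assigned or not membership.get(seed):
            continue
        group = [seed]
        assigned.add(seed)
        for other in order:
            if other in assigned or not membership.get(other):
                continue
            a, b = membership[seed], membership[other]
            jac = len(a & b) / len(a | b) if a | b else 0.0
            if jac >= jaccard_min:
                group.append(other)
                assigned.add(other)
        score = cluster_score([float(enrich.loc[s, "p_ease"]) for s in group])
        clusters.append(AnnotationCluster(name=seed, members=group, score=score))
    return clusters


def upstream_z(
    de: pd.DataFrame,
    net: RegulatorNetwork,
    level: str = "L1",
    min_targets: int = 3,
    z_cut: float = 2.0,
) -> pd.DataFrame:
    """Directional activation score per regulator.

    Only targets at the given significance level contribute; the observed
    sign is the sign of the probe's fold change. Regulators with fewer
    than ``min_targets`` usable edges are omitted from the table.
    """
    sig = de[de["level"] == level]
    if "symbol" in de.columns:
        observed = {
            _norm(s): float(np.sign(d))
            for s, d in zip(sig["symbol"], sig["delta"])
            if isinstance(s, str)
        }
    else:
        observed = {
            _norm(str(p)): float(np.sign(d))
            for p, d in zip(sig.index, sig["delta"])
        }

    rows = []
    for reg in net.regulators:
        signs = [
            exp_sign * observed[_norm(t)]
            for t, exp_sign in net.targets_of(reg)
            if _norm(t) in observed and observed[_norm(t)] != 0
        ]
        n = len(signs)
        if n < min_targets:
            continue
        z = float(np.sum(signs) / np.sqrt(n))
        call = "activated" if z >= z_cut else "inhibited" if z <= -z_cut else "none"
        rows.append({"regulator": reg, "z": z, "n_targets_used": n, "call": call})
    if not rows:
        return pd.DataFrame(columns=["z", "n_targets_used", "call"])
    return pd.DataFrame(rows).set_index("regulator")
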