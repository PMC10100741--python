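"""Coevolution networks: communities, TSDS structure, and motif effects.

Alignment columns are nodes and CRPs are edges.  Communities are found by
greedy (Clauset-Newman-Moore) modularity maximization.  TSDS clustering in
the network is tested by permuting TSDS labels over nodes; CRP fractions are
classified by how many endpoints are TSDSs; sequence separation and
block-crossing fractions follow the > 5-position and column-interval rules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import ttest_ind
from statsmodels.stats.multitest import multipletests

from .motifs import MotifSimilarityMatrix
from .msa import GAP, AlignedFamily

Pair = tuple[int, int]
SEPARATION_THRESHOLD = 5  # CRPs > 5 alignment positions apart are "distant"


@dataclass
class ResidueNetwork:
    graph: nx.Graph
    tsds: set[int]
    communities: dict[int, int] | None = None
    modularity: float | None = None


def build_network(crps: set[Pair], tsds: set[int]) -> ResidueNetwork:
    g = nx.Graph()
    g.add_edges_from(crps)
    for node in g.nodes:
        g.nodes[node]["is_tsds"] = node in tsds
    return ResidueNetwork(g, set(tsds))


def detect_communities(net: ResidueNetwork) -> tuple[dict[int, int], float]:
    """Greedy modularity communities and the partition's modularity."""
    g = net.graph
    if g.number_of_edges() == 0:
        raise ValueError("cannot detect communities in an edgeless graph")
    comms = nx.community.greedy_modularity_communities(g)
    mapping = {n: i for i, c in enumerate(comms) for n in c}
    q = nx.community.modularity(g, comms)
    net.communities = mapping
    net.modularity = q
    return mapping, q


def classify_crps(crps: set[Pair], tsds: set[int]) -> dict:
    """CRP fractions by TSDS membership of the two endpoints.

    intra: both endpoints TSDS; between: exactly one; extra: neither.
    Fractions are exact ratios of counts and sum to 1.
    """
    n = len(crps)
    counts = {"intra": 0, "between": 0, "extra": 0}
    for i, j in crps:
        k = (i in tsds) + (j in tsds)
        counts[("extra", "between", "intra")[k]] += 1
    fractions = {
        key: (Fraction(c, n) if n else Fraction(0)) for key, c in counts.items()
    }
    return {
        "counts": counts,
        "fractions": {k: float(v) for k, v in fractions.items()},
        "fractions_exact": fractions,
        "n_crps": n,
    }


def tsds_clustering_test(
    net: ResidueNetwork,
    n_perm: int = 1000,
    seed: int | None = None,
) -> dict:
    """Do TSDSs coevolve with TSDSs more than label-shuffling predicts?

    The statistic is the fraction of edges with both endpoints TSDS; the null
    permutes the TSDS labels over the network's nodes, preserving the number
    of labelled nodes and the topology.
    """
    g = net.graph
    nodes = list(g.nodes)
    tsds = net.tsds & set(nodes)
    edges = list(g.edges)
    if not edges:
        raise ValueError("network has no edges")
    n_tsds = len(tsds)

    def intra_fraction(labelled: set[int]) -> float:
        hits = sum(1 for u, v in edges if u in labelled and v in labelled)
        return hits / len(edges)

    observed = intra_fraction(tsds)
    rng = np.random.default_rng(seed)
    node_arr = np.array(nodes)
    exceed = 0
    for _ in range(n_perm):
        perm = set(rng.choice(node_arr, size=n_tsds, replace=False).tolist())
        if intra_fraction(perm) >= observed:
            exceed += 1
    p = (1 + exceed) / (n_perm + 1)
    return {
        "observed_intra_fraction": observed,
        "n_tsds_nodes": n_tsds,
        "n_edges": len(edges),
        "p_value": p,
    }


def separation_and_blocks(
    crps: set[Pair],
    blocks: list[tuple[int, int]] | None = None,
) -> dict:
    """Sequence separation and block-crossing fractions of the CRP set.

    ``frac_distant``: CRPs whose endpoints are more than 5 alignment
    positions apart.  ``frac_out_of_block``: CRPs whose endpoints fall in
    different blocks (inclusive column intervals); an endpoint outside every
    block counts as out-of-block.
    """
    if not crps:
        raise ValueError("empty CRP set")
    n = len(crps)
    distant = sum(1 for i, j in crps if abs(i - j) > SEPARATION_THRESHOLD)
    out: dict = {"frac_distant": distant / n, "n_crps": n}
    if blocks is not None:
        _check_blocks(blocks)

        def block_of(c: int) -> int | None:
            for b, (lo, hi) in enumerate(blocks):
                if lo <= c <= hi:
                    return b
            return None

        crossing = 0
        for i, j in crps:
            bi, bj = block_of(i), block_of(j)
            if bi is None or bj is None or bi != bj:
                crossing += 1
        out["frac_out_of_block"] = crossing / n
    return out


def _check_blocks(blocks: list[tuple[int, int]]) -> None:
    spans = sorted(blocks)
    for (lo, hi) in spans:
        if hi < lo:
            raise ValueError(f"invalid block interval ({lo}, {hi})")
    for (_, hi_a), (lo_b, _) in zip(spans, spans[1:]):
        if lo_b <= hi_a:
            raise ValueError("blocks must be disjoint intervals")


def default_blocks(msa: AlignedFamily, gap_threshold: float = 0.5) -> list[tuple[int, int]]:
    """Heuristic blocks: maximal runs of columns with gap fraction <= 0.5."""
    gappy = msa.gap_fraction() > gap_threshold
    blocks = []
    start = None
    for c in range(msa.n_col):
        if not gappy[c] and start is None:
            start = c
        elif gappy[c] and start is not None:
            blocks.append((start, c - 1))
            start = None
    if start is not None:
        blocks.append((start, msa.n_col - 1))
    return blocks


def _pair_motif_score(
    i: int,
    j: int,
    msa: AlignedFamily,
    sims: MotifSimilarityMatrix,
) -> float | None:
    """Residue-pair-weighted motif similarity for one column pair.

    TFs are grouped by their ordered residue pair at columns (i, j); each
    group with >= 2 members contributes its mean pairwise motif similarity,
    weighted by group size over the total of eligible TFs.
    """
    groups: dict[tuple[str, str], list[str]] = {}
    for tf in msa.ids:
        row = msa.row(tf)
        a, b = row[i], row[j]
        if a == GAP or b == GAP:
            continue
        groups.setdefault((a, b), []).append(tf)
    eligible = {k: v for k, v in groups.items() if len(v) >= 2}
    total = sum(len(v) for v in eligible.values())
    if total == 0:
        return None
    score = 0.0
    for members in eligible.values():
        sub = sims.submatrix(members)
        score += (len(members) / total) * float(sub.off_diagonal().mean())
    return score


def crp_grouped_motif_similarity(
    crps: set[Pair],
    non_crps: set[Pair],
    msa: AlignedFamily,
    sims: MotifSimilarityMatrix,
) -> dict:
    """Compare motif similarity of CRP-grouped vs non-CRP-grouped TFs.

    Each pair's score is the group-size-weighted mean of within-group motif
    similarities (groups = TFs sharing the ordered residue pair at the two
    columns).  CRP and non-CRP score distributions are compared with a Welch
    two-sample t-test.
    """
    crp_scores = [
        s for p in sorted(crps) if (s := _pair_motif_score(*p, msa, sims)) is not None
    ]
    non_scores = [
        s
        for p in sorted(non_crps)
        if (s := _pair_motif_score(*p, msa, sims)) is not None
    ]
    report: dict = {
        "crp_scores": crp_scores,
        "non_crp_scores": non_scores,
        "crp_mean": float(np.mean(crp_scores)) if crp_scores else None,
        "non_crp_mean": float(np.mean(non_scores)) if non_scores else None,
    }
    if len(crp_scores) >= 2 and len(non_scores) >= 2:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            stat, p = ttest_ind(crp_scores, non_scores, equal_var=False)
        report["t_statistic"] = None if np.isnan(stat) else float(stat)
        report["p_value"] = None if np.isnan(p) else float(p)
        report["direction"] = (
            "crp_higher" if report["crp_mean"] > report["non_crp_mean"]
            else "non_crp_higher"
            if report["crp_mean"] < report["non_crp_mean"]
            else "equal"
        )
    else:
        report["t_statistic"] = None
        report["p_value"] = None
        report["direction"] = None
    return report


def adjust_fdr(p_values: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if len(p) == 0:
        return []
    return multipletests(p, method="fdr_bh")[1].tolist()


def write_edge_list(net: ResidueNetwork, path) -> None:
    rows = [
        {
            "col_i": u,
            "col_j": v,
            "tsds_i": u in net.tsds,
            "tsds_j": v in net.tsds,
        }
        for u, v in sorted(net.graph.edges)
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_graphml(net: ResidueNetwork, path) -> None:
    g = net.graph.copy()
    if net.communities:
        for n, c in net.communities.items():
            g.nodes[n]["community"] = c
    nx.write_graphml(g, str(path))
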