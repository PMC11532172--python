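"""GRN assembly: combine co-expression weights, mutual ranks, and TF→promoter
evidence into a pruned, thresholded regulatory network.

An edge between two genes of the differential-expression set survives
pruning only if at least one of the pair is a transcription factor with a
cis-regulatory-element (PWM) hit in the other gene's promoter.  Retained
edges carry the TOM weight, the normalized mutual rank, the correlation
sign, and the support direction(s).  The final network keeps edges with
weight > 0.1 and mutual rank > 0.98 (strict), and ego ("first-neighbor")
modules around seed TFs collect positively-signed activator/activated
partners.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .network import WeightedNetwork

logger = logging.getLogger(__name__)

DEFAULT_MIN_WEIGHT = 0.1
DEFAULT_MIN_MR = 0.98


@dataclass(frozen=True)
class GRNEdge:
    """A retained network edge; gene_a < gene_b lexicographically.

    ``support`` holds the TF→target direction(s) with promoter evidence:
    a subset of {"a->b", "b->a"}.
    """

    gene_a: str
    gene_b: str
    weight: float
    mutual_rank: float
    sign: int
    support: frozenset[str]

    def __post_init__(self):
        if self.gene_a >= self.gene_b:
            raise ValueError("gene_a must sort before gene_b")
        if not self.support <= {"a->b", "b->a"} or not self.support:
            raise ValueError("support must be a non-empty subset of directions")


@dataclass
class GRNModule:
    seed: str
    direction: str                     # activators_of | activated_by | both
    members: set[str]
    edges: list[GRNEdge]


def build_grn(tom_net: WeightedNetwork, mr: pd.DataFrame, de_genes: set[str],
              tf_targets: dict[tuple[str, str], object] | set[tuple[str, str]],
              ) -> list[GRNEdge]:
    """Prune the co-expression network to TF-supported edges among DE genes.

    A pair (i, j) is kept iff i is a TF with a promoter hit in j or vice
    versa; self pairs are ignored for edge purposes.  Genes left without any
    edge drop off the roster (they simply appear in no edge).
    """
    de_genes = set(de_genes)
    absent = de_genes - set(tom_net.genes)
    if absent:
        raise KeyError(f"DE genes missing from network: {sorted(absent)[:5]}")
    pair_set = set(tf_targets)
    if not pair_set:
        logger.warning("empty TF→target map: resulting GRN has no edges")
        return []
    genes = sorted(de_genes & set(mr.index))
    idx = tom_net.index_of(genes)
    w = tom_net.weights[np.ix_(idx, idx)]
    s = tom_net.corr_sign[np.ix_(idx, idx)]
    mrm = mr.loc[genes, genes].to_numpy()
    edges: list[GRNEdge] = []
    for ia, a in enumerate(genes):
        for ib in range(ia + 1, len(genes)):
            b = genes[ib]
            support = set()
            if (a, b) in pair_set:
                support.add("a->b")
            if (b, a) in pair_set:
                support.add("b->a")
            if not support:
                continue
            edges.append(GRNEdge(a, b, float(w[ia, ib]), float(mrm[ia, ib]),
                                 int(s[ia, ib]), frozenset(support)))
    return edges


def threshold_network(edges: list[GRNEdge], min_weight: float = DEFAULT_MIN_WEIGHT,
                      min_mr: float = DEFAULT_MIN_MR) -> list[GRNEdge]:
    """Strict filters: weight > min_weight AND mutual_rank > min_mr."""
    return [e for e in edges if e.weight > min_weight and e.mutual_rank > min_mr]


def ego_module(edges: list[GRNEdge], seed: str, direction: str = "both") -> GRNModule:
    """First-neighbor module around a seed gene, following activation signs.

    ``activated_by``: partners the seed has TF support toward, positive sign
    (genes activated by the seed).  ``activators_of``: partners with TF
    support toward the seed, positive sign.  ``both``: union.
    """
    if direction not in {"activators_of", "activated_by", "both"}:
        raise ValueError(f"unknown direction {direction!r}")
    roster = {g for e in edges for g in (e.gene_a, e.gene_b)}
    if seed not in roster:
        raise KeyError(f"seed gene {seed!r} not in the edge roster")
    members: set[str] = set()
    kept: list[GRNEdge] = []
    for e in edges:
        if seed not in (e.gene_a, e.gene_b) or e.sign != 1:
            continue
        partner = e.gene_b if e.gene_a == seed else e.gene_a
        outward = "a->b" if e.gene_a == seed else "b->a"   # seed → partner
        inward = "b->a" if e.gene_a == seed else "a->b"    # partner → seed
        take = (
            (direction in ("activated_by", "both") and outward in e.support)
            or (direction in ("activators_of", "both") and inward in e.support)
        )
        if take:
            members.add(partner)
            kept.append(e)
    return GRNModule(seed, direction, members, kept)


# -- export --------------------------------------------------------------------


def edges_to_table(edges: list[GRNEdge]) -> pd.DataFrame:
    rows = [{
        "gene_a": e.gene_a, "gene_b": e.gene_b, "weight": e.weight,
        "mutual_rank": e.mutual_rank, "sign": e.sign,
        "support": ";".join(sorted(e.support)),
    } for e in edges]
    return pd.DataFrame(rows, columns=["gene_a", "gene_b", "weight",
                                       "mutual_rank", "sign", "support"])


def edges_from_table(table: pd.DataFrame) -> list[GRNEdge]:
    return [GRNEdge(r.gene_a, r.gene_b, float(r.weight), float(r.mutual_rank),
                    int(r.sign), frozenset(str(r.support).split(";")))
            for r in table.itertuples(index=False)]


def to_graphml(edges: list[GRNEdge], path) -> None:
    g = nx.Graph()
    for e in edges:
        g.add_edge(e.gene_a, e.gene_b, weight=e.weight, mutual_rank=e.mutual_rank,
                   sign=e.sign, support=";".join(sorted(e.support)))
    nx.write_graphml(g, path)
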