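"""Weighted co-expression network: soft-thresholded Pearson adjacency,
topological overlap, and the normalized mutual-rank edge statistic.

The adjacency is unsigned, a_ij = |cor(x_i, x_j)|^β, with the soft power β
chosen so the network's connectivity distribution is closest to scale-free
(signed R² of the log-log frequency/connectivity fit nearest 0.9).  The
topological overlap matrix (TOM)

    ω_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
    ℓ_ij = Σ_{u≠i,j} a_iu a_uj,   k_i = Σ_{u≠i} a_iu

credits shared neighbours and is the edge weight carried into the GRN.  The
mutual rank of a pair is the geometric mean of each gene's percentile rank
in the other gene's weight-ordered partner list, normalised to (0, 1] with
1 = mutually top-ranked, so the retention rule "mutual rank > 0.98" keeps
only mutually high-ranked edges.

The sign of the underlying correlation is carried alongside the unsigned
weights so GRN edges can later be labelled activating or repressing.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

logger = logging.getLogger(__name__)

DEFAULT_POWERS = tuple(range(1, 21))
N_CONNECTIVITY_BINS = 10


@dataclass
class WeightedNetwork:
    """Symmetric gene × gene weight matrix plus correlation signs."""

    genes: list[str]
    weights: np.ndarray           # symmetric, off-diagonal in [0, 1]
    kind: str                     # "adjacency" | "TOM"
    beta: float
    corr_sign: np.ndarray         # symmetric entries in {-1, 0, +1}

    def __post_init__(self):
        w = self.weights
        if w.shape != (len(self.genes), len(self.genes)):
            raise ValueError("weight matrix shape does not match gene list")
        if not np.allclose(w, w.T, atol=1e-10):
            raise ValueError("weight matrix must be symmetric")
        off = w[~np.eye(len(self.genes), dtype=bool)]
        if off.size and (off.min() < -1e-12 or off.max() > 1 + 1e-12):
            raise ValueError("off-diagonal weights must lie in [0, 1]")

    def index_of(self, genes: list[str]) -> np.ndarray:
        pos = {g: i for i, g in enumerate(self.genes)}
        try:
            return np.array([pos[g] for g in genes])
        except KeyError as exc:
            raise KeyError(f"gene {exc.args[0]!r} not in network") from None


def pearson_adjacency(expr: pd.DataFrame, beta: float) -> WeightedNetwork:
    """Unsigned soft-thresholded adjacency from a genes × samples matrix.

    a_ij = |cor|^β with the diagonal zeroed; the correlation sign is kept
    separately.  Zero-variance genes make the correlation undefined and are
    rejected by name.
    """
    if beta <= 0:
        raise ValueError("soft power beta must be positive")
    x = expr.to_numpy(dtype=float)
    if x.shape[1] < 3:
        raise ValueError("need ≥3 samples for a meaningful correlation")
    sd = x.std(axis=1)
    if (sd == 0).any():
        bad = expr.index[sd == 0][0]
        raise ValueError(f"zero-variance gene {bad!r}")
    corr = np.corrcoef(x)
    corr = np.clip(corr, -1.0, 1.0)
    adj = np.abs(corr) ** beta
    np.fill_diagonal(adj, 0.0)
    sign = np.sign(corr).astype(np.int8)
    return WeightedNetwork(list(expr.index), adj, "adjacency", float(beta), sign)


def scale_free_fit(connectivity: np.ndarray, n_bins: int = N_CONNECTIVITY_BINS) -> float:
    """Signed R² of the log10(frequency) ~ log10(mean k) fit over k bins.

    Connectivities are binned into ``n_bins`` equal-width bins of log10(k);
    the fit regresses the log of the per-bin frequency on the log of the
    per-bin mean connectivity, and the R² is signed by the negated slope so
    only decreasing (scale-free-like) fits count positively.
    """
    k = connectivity[connectivity > 0]
    if k.size < 3 or np.isclose(k.min(), k.max()):
        raise ValueError("degenerate connectivity distribution")
    logk = np.log10(k)
    edges = np.linspace(logk.min(), logk.max(), n_bins + 1)
    idx = np.clip(np.digitize(logk, edges[1:-1]), 0, n_bins - 1)
    xs, ys = [], []
    for b in range(n_bins):
        mask = idx == b
        if not mask.any():
            continue
        xs.append(np.log10(np.mean(k[mask])))
        ys.append(np.log10(mask.sum() / k.size))
    if len(xs) < 3:
        raise ValueError("degenerate connectivity binning")
    slope, intercept = np.polyfit(xs, ys, 1)
    resid = np.array(ys) - (slope * np.array(xs) + intercept)
    ss_tot = np.sum((np.array(ys) - np.mean(ys)) ** 2)
    r2 = 1.0 - np.sum(resid**2) / ss_tot if ss_tot > 0 else 0.0
    return float(-np.sign(slope) * r2)


def pick_soft_threshold(expr: pd.DataFrame, powers=DEFAULT_POWERS,
                        target_r2: float = 0.9,
                        return_table: bool = False):
    """Soft power whose signed scale-free R² is closest to *target_r2*.

    Ties break toward the smaller power; powers with degenerate
    connectivity binning are skipped with a warning.
    """
    powers = list(powers)
    if not powers:
        raise ValueError("no candidate powers supplied")
    x = expr.to_numpy(dtype=float)
    corr = np.abs(np.clip(np.corrcoef(x), -1.0, 1.0))
    np.fill_diagonal(corr, 0.0)
    rows = []
    for p in sorted(powers):
        adj = corr**p
        k = adj.sum(axis=1)
        try:
            r2 = scale_free_fit(k)
        except ValueError:
            warnings.warn(f"power {p}: degenerate connectivity distribution, skipped")
            continue
        rows.append((p, r2, float(k.mean())))
    if not rows:
        raise ValueError("all candidate powers degenerate")
    table = pd.DataFrame(rows, columns=["power", "signed_r2", "mean_k"])
    best = table.iloc[int(np.argmin(np.abs(table["signed_r2"] - target_r2)))]
    beta = float(best["power"])
    return (beta, table) if return_table else beta


def tom(adjacency: WeightedNetwork) -> WeightedNetwork:
    """Topological overlap matrix from an adjacency network.

    ω_ij = (ℓ_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij); diagonal set to 1 by
    convention and excluded from edge operations.
    """
    if adjacency.kind != "adjacency":
        raise ValueError("tom() expects an adjacency network")
    a = adjacency.weights
    # with a zero diagonal, (A @ A)_ij already equals Σ_{u≠i,j} a_iu a_uj
    l = a @ a
    k = a.sum(axis=1)
    kmin = np.minimum.outer(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        omega = (l + a) / (kmin + 1.0 - a)
    np.fill_diagonal(omega, 1.0)
    omega = np.clip((omega + omega.T) / 2.0, 0.0, 1.0)  # symmetrise roundoff
    return WeightedNetwork(adjacency.genes, omega, "TOM", adjacency.beta,
                           adjacency.corr_sign.copy())


def mutual_rank(network: WeightedNetwork, gene_subset: list[str] | None = None,
                convention: str = "percentile") -> pd.DataFrame:
    """Mutual rank for every unordered pair in *gene_subset*.

    Within the subset, gene i ranks its partners by descending weight
    (rank 1 = strongest, ties get the mean rank).  Under the default
    ``percentile`` convention the rank becomes
    r_i(j) = (N − rank_i(j) + 1)/N with N = |subset| − 1 and
    MR(i, j) = sqrt(r_i(j) · r_j(i)) ∈ (0, 1], 1 = mutually top-ranked —
    the form a high-is-good retention cut (MR > 0.98) expects.  The
    ``raw`` convention returns the classical low-is-good geometric mean of
    the two ranks, sqrt(rank_i(j) · rank_j(i)) ∈ [1, N].

    Returns a square DataFrame (diagonal 1 resp. 0) indexed by the subset.
    """
    if convention not in {"percentile", "raw"}:
        raise ValueError(f"unknown mutual-rank convention {convention!r}")
    genes = list(gene_subset) if gene_subset is not None else list(network.genes)
    if len(genes) < 2:
        raise ValueError("mutual rank needs ≥2 genes")
    idx = network.index_of(genes)
    w = network.weights[np.ix_(idx, idx)]
    n = len(genes)
    big = n - 1
    ranks = np.empty((n, n))
    mask = ~np.eye(n, dtype=bool)
    for i in range(n):
        partners = w[i][mask[i]]
        ranks[i][mask[i]] = rankdata(-partners, method="average")
    if convention == "raw":
        mr = np.sqrt(ranks * ranks.T)
        np.fill_diagonal(mr, 0.0)
    else:
        pct = (big - ranks + 1.0) / big
        mr = np.sqrt(pct * pct.T)
        np.fill_diagonal(mr, 1.0)
    return pd.DataFrame(mr, index=genes, columns=genes)


def network_edge_table(tom_net: WeightedNetwork, mr: pd.DataFrame) -> pd.DataFrame:
    """Long-format edge list (gene_a < gene_b) of weight, mutual rank, sign."""
    genes = list(mr.index)
    idx = tom_net.index_of(genes)
    w = tom_net.weights[np.ix_(idx, idx)]
    s = tom_net.corr_sign[np.ix_(idx, idx)]
    iu = np.triu_indices(len(genes), k=1)
    return pd.DataFrame({
        "gene_a": [genes[i] for i in iu[0]],
        "gene_b": [genes[j] for j in iu[1]],
        "weight": w[iu],
        "mutual_rank": mr.to_numpy()[iu],
        "corr_sign": s[iu].astype(int),
    })
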