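"""Expression-cohort discovery on stage profiles.

Genes are summarised as the median TPM per developmental stage (across
replicates), z-scaled per gene, and clustered with k-means.  The number of
cohorts is chosen by the within-cluster-sum-of-squares elbow, formalised as
the k with the largest second difference of the WSS curve.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

from .expression import ExpressionMatrix, NRB

logger = logging.getLogger(__name__)

N_RESTARTS = 25


@dataclass
class StageProfileMatrix:
    """Gene × stage matrix of z-scaled stage medians.

    ``constant_genes`` lists genes whose stage medians were constant: they
    cannot be scaled and are excluded from clustering.
    """

    values: pd.DataFrame          # scaled profiles, constant genes dropped
    stages: list[int]
    constant_genes: list[str]


def zscale_rows(df: pd.DataFrame) -> pd.DataFrame:
    """Scale each row to mean 0, sd 1 (ddof=1, matching R's ``scale``)."""
    mu = df.mean(axis=1)
    sd = df.std(axis=1, ddof=1)
    return df.sub(mu, axis=0).div(sd, axis=0)


def stage_profiles(tpm: ExpressionMatrix, genes: list[str] | None = None,
                   tissue_class: str = NRB) -> StageProfileMatrix:
    """Median-over-replicates stage profile per gene, z-scaled per gene."""
    genes = list(genes) if genes is not None else tpm.genes
    absent = [g for g in genes if g not in tpm.values.index]
    if absent:
        raise KeyError(f"genes absent from matrix: {absent[:5]}")
    stages = tpm.stages(tissue_class)
    if not stages:
        raise ValueError(f"no staged samples of class {tissue_class!r}")
    med = pd.DataFrame(
        {s: tpm.values.loc[genes, tpm.samples_where(tissue_class, s)].median(axis=1)
         for s in stages}
    )
    sd = med.std(axis=1, ddof=1)
    constant = list(med.index[sd == 0])
    if constant:
        logger.warning("%d constant gene(s) excluded from cohort clustering", len(constant))
    keep = med.drop(index=constant)
    return StageProfileMatrix(zscale_rows(keep), stages, constant)


@dataclass
class CohortAssignment:
    labels: pd.Series             # gene → cohort label in 1..k
    k: int
    wss: float
    centers: np.ndarray           # k × n_stages, in renumbered label order


def _wss_curve(x: np.ndarray, k_max: int, seed: int) -> np.ndarray:
    wss = np.empty(k_max)
    for k in range(1, k_max + 1):
        km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed)
        km.fit(x)
        wss[k - 1] = km.inertia_
    return wss


def choose_k_wss(profiles: StageProfileMatrix, k_max: int = 10, seed: int = 0,
                 return_curve: bool = False):
    """Elbow choice of k: argmax of the WSS second difference.

    WSS is recorded for k = 1..k_max (25 k-means++ restarts each, fixed
    seed); the elbow is the k maximising WSS(k−1) − 2·WSS(k) + WSS(k+1)
    over k = 2..k_max−1.
    """
    if k_max < 3:
        raise ValueError("k_max must be ≥3 so an interior elbow exists")
    x = profiles.values.to_numpy()
    if x.shape[0] < k_max:
        raise ValueError(f"only {x.shape[0]} genes but k_max={k_max}")
    wss = _wss_curve(x, k_max, seed)
    second_diff = wss[:-2] - 2 * wss[1:-1] + wss[2:]   # index i ↔ k = i + 2
    k = int(np.argmax(second_diff)) + 2
    return (k, wss) if return_curve else k


def kmeans_cohorts(profiles: StageProfileMatrix, k: int, seed: int = 0) -> CohortAssignment:
    """Lloyd's k-means (k-means++, 25 restarts) into expression cohorts.

    Labels are renumbered 1..k by descending cluster size; size ties break
    on the lexicographically smallest member gene ID.
    """
    if k < 1:
        raise ValueError("k must be ≥1")
    x = profiles.values.to_numpy()
    km = KMeans(n_clusters=k, n_init=N_RESTARTS, random_state=seed)
    raw = km.fit_predict(x)
    genes = list(profiles.values.index)
    order = sorted(
        range(k),
        key=lambda c: (-(raw == c).sum(), min(g for g, lab in zip(genes, raw) if lab == c)),
    )
    remap = {old: new + 1 for new, old in enumerate(order)}
    labels = pd.Series([remap[c] for c in raw], index=genes, name="cohort")
    centers = km.cluster_centers_[order]
    return CohortAssignment(labels, k, float(km.inertia_), centers)
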