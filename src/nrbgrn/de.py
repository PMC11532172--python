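"""Two-stage differential expression with fold-change + adjusted-p filtering.

Stage one contrasts pooled nodal-root-bud (NRB) pulvinus samples against
pooled internode rind controls and keeps genes up-regulated in NRBs with a
fold change > 5 and Benjamini–Hochberg adjusted p < 0.05.  Stage two runs all
pairwise contrasts between NRB developmental stages (phytomers) and keeps
genes with |fold change| > 5 and adjusted p < 0.05 in any pair.  The
intersection of the two sets is the NRB-development gene set fed to network
construction.

The per-gene test is Welch's unequal-variance t on log2(TPM+1); fold changes
are ratios of pseudocounted group means on the linear TPM scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionMatrix, NRB, INTERNODE

PSEUDOCOUNT = 1.0  # TPM added before ratios/logs; fixed for reproducibility


@dataclass(frozen=True)
class Contrast:
    """A named two-group comparison (A over B) on sample ID subsets."""

    name: str
    group_a: tuple[str, ...]
    group_b: tuple[str, ...]

    def __post_init__(self):
        a, b = set(self.group_a), set(self.group_b)
        if not a or not b:
            raise ValueError(f"contrast {self.name!r}: both groups must be non-empty")
        if a & b:
            raise ValueError(f"contrast {self.name!r}: groups overlap")
        if len(a) < 2 or len(b) < 2:
            raise ValueError(f"contrast {self.name!r}: each group needs ≥2 samples")


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values, order-preserving.

    padj_(i) = min_{j ≥ i} ( m · p_(j) / j ), clipped at 1.
    """
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise ValueError("expected a 1-D p-value vector")
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]  # enforce monotonicity
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def de_test(tpm: ExpressionMatrix, contrast: Contrast) -> pd.DataFrame:
    """Per-gene Welch test and pseudocounted fold change for one contrast.

    Returns a DataFrame indexed by gene with columns ``log2fc`` (A over B),
    ``fc`` (linear ratio), ``p``, ``padj``.  Degenerate genes (zero variance
    in both groups, identical means) get p = 1; zero variance with different
    means gives p = 0.
    """
    a = tpm.values[list(contrast.group_a)].to_numpy(dtype=float)
    b = tpm.values[list(contrast.group_b)].to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    fc = (mean_a + PSEUDOCOUNT) / (mean_b + PSEUDOCOUNT)
    log2fc = np.log2(fc)

    la, lb = np.log2(a + PSEUDOCOUNT), np.log2(b + PSEUDOCOUNT)
    with np.errstate(invalid="ignore", divide="ignore"):
        res = stats.ttest_ind(la, lb, axis=1, equal_var=False)
        p = np.asarray(res.pvalue, dtype=float)
    var_a, var_b = la.var(axis=1, ddof=1), lb.var(axis=1, ddof=1)
    degenerate = (var_a == 0) & (var_b == 0)
    same = degenerate & np.isclose(la.mean(axis=1), lb.mean(axis=1))
    p[degenerate & ~same] = 0.0
    p[same] = 1.0
    p = np.nan_to_num(p, nan=1.0)

    out = pd.DataFrame(
        {"log2fc": log2fc, "fc": fc, "p": p, "padj": bh_adjust(p)},
        index=tpm.values.index,
    )
    out.index.name = "gene"
    return out


def apply_de_filter(table: pd.DataFrame, fc: float = 5.0, alpha: float = 0.05,
                    direction: str = "up") -> pd.DataFrame:
    """Add a ``passes`` flag: fold change beyond *fc* (strict) and padj < alpha.

    direction="up" requires fc on the linear scale strictly above the
    threshold; direction="both" accepts either direction (|log2 fc| filter).
    """
    if direction == "up":
        fc_ok = table["fc"] > fc
    elif direction == "both":
        fc_ok = (table["fc"] > fc) | (table["fc"] < 1.0 / fc)
    else:
        raise ValueError("direction must be 'up' or 'both'")
    table = table.copy()
    table["passes"] = fc_ok & (table["padj"] < alpha)
    return table


def nrb_specific_genes(tpm: ExpressionMatrix, fc: float = 5.0, alpha: float = 0.05,
                       return_table: bool = False):
    """Stage-one DE: genes up-regulated in pooled NRB vs pooled internode rind."""
    nrb = tpm.samples_where(tissue_class=NRB)
    ctrl = tpm.samples_where(tissue_class=INTERNODE)
    if not nrb or not ctrl:
        raise ValueError("both NRB and internode sample classes are required")
    contrast = Contrast("NRB_vs_internode", tuple(nrb), tuple(ctrl))
    table = apply_de_filter(de_test(tpm, contrast), fc=fc, alpha=alpha, direction="up")
    genes = set(table.index[table["passes"]])
    return (genes, table) if return_table else genes


def stagewise_degs(tpm: ExpressionMatrix, fc: float = 5.0, alpha: float = 0.05,
                   return_tables: bool = False):
    """Stage-two DE: union over all pairwise NRB stage contrasts (|FC| > fc).

    BH adjustment is applied within each pairwise contrast.
    """
    stages = tpm.stages(NRB)
    if len(stages) < 2:
        raise ValueError("need ≥2 NRB stages for pairwise contrasts")
    groups = {s: tpm.samples_where(tissue_class=NRB, stage=s) for s in stages}
    for s, members in groups.items():
        if len(members) < 2:
            raise ValueError(f"stage {s} has <2 replicates")
    genes: set[str] = set()
    tables: dict[str, pd.DataFrame] = {}
    for s1, s2 in combinations(stages, 2):
        contrast = Contrast(f"stage_{s1}_vs_{s2}", tuple(groups[s1]), tuple(groups[s2]))
        table = apply_de_filter(de_test(tpm, contrast), fc=fc, alpha=alpha, direction="both")
        genes |= set(table.index[table["passes"]])
        if return_tables:
            tables[contrast.name] = table
    return (genes, tables) if return_tables else genes


def intersect_deg_sets(set_a: set[str], set_b: set[str]) -> set[str]:
    """The NRB-development gene set: genes differential in both analyses."""
    return set(set_a) & set(set_b)
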