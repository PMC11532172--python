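"""Planted-truth benchmarks: run the analysis in memory and score recovery.

These helpers drive the same stage functions as the pipeline (TPM → two-stage
DE → network → scan → GRN) on a simulated study and compare the result with
the truth ledger.  They back both the validation test-suite and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import network as net_mod
from .de import intersect_deg_sets, nrb_specific_genes, stagewise_degs
from .grn import build_grn, threshold_network
from .motifs import Promoter, tf_target_map
from .quantify import expression_floor, tpm_normalize
from .simulate import SimulationConfig, SimulatedStudy, simulate_counts, simulate_study


@dataclass
class GRNBenchmark:
    seed: int
    beta: float
    n_de: int
    n_planted: int
    n_retained: int
    recovery: float           # fraction of planted TF→target pairs retained
    spurious: float           # fraction of retained edges that are unplanted


def de_benchmark(seed: int, **config_kwargs) -> tuple[float, float]:
    """(sensitivity, false-discovery proportion) of the NRB-specific stage."""
    cfg = SimulationConfig(seed=seed, **config_kwargs)
    counts, ledger = simulate_counts(cfg)
    tpm = tpm_normalize(counts)
    floored = tpm.subset_genes(expression_floor(tpm, 5.0))
    called = nrb_specific_genes(floored)
    truth = ledger.de_tissue
    sens = len(called & truth) / len(truth) if truth else float("nan")
    fdp = len(called - truth) / len(called) if called else 0.0
    return sens, fdp


def null_pass_fraction(seed: int, n_genes: int = 2000) -> float:
    """Fraction of genes passing the joint FC/padj filter with nothing planted."""
    cfg = SimulationConfig(seed=seed, n_genes=n_genes,
                           frac_de_tissue=0.0, frac_de_stage=0.0)
    counts, _ = simulate_counts(cfg)
    tpm = tpm_normalize(counts)
    floored = tpm.subset_genes(expression_floor(tpm, 5.0))
    called = nrb_specific_genes(floored)
    return len(called) / len(floored.genes)


def analyse_study(study: SimulatedStudy, *, tpm_floor: float = 5.0, fc: float = 5.0,
                  alpha: float = 0.05, rel_threshold: float = 0.85,
                  min_weight: float = 0.1, min_mr: float = 0.98) -> dict:
    """Run TPM → DE → network → scan → GRN in memory; return the artifacts."""
    tpm = tpm_normalize(study.counts)
    floored = tpm.subset_genes(expression_floor(tpm, tpm_floor))
    nrb_set = nrb_specific_genes(floored, fc=fc, alpha=alpha)
    stage_set = stagewise_degs(floored, fc=fc, alpha=alpha)
    de_genes = intersect_deg_sets(nrb_set, stage_set)

    nrb_samples = floored.samples_where(tissue_class="NRB")
    log_expr = np.log2(floored.values[nrb_samples] + 1.0)
    beta = net_mod.pick_soft_threshold(log_expr)
    tom_net = net_mod.tom(net_mod.pearson_adjacency(log_expr, beta))
    mr = net_mod.mutual_rank(tom_net, sorted(de_genes))

    promoters = {g: Promoter(g, s, "synthetic", 0, len(s), "+")
                 for g, s in study.genome.promoters.items() if g in de_genes}
    pair_hits = tf_target_map(study.tf_table, promoters, study.pwms, rel_threshold)
    edges = build_grn(tom_net, mr, de_genes, pair_hits)
    kept = threshold_network(edges, min_weight, min_mr)
    return {"tpm": tpm, "floored": floored, "nrb_set": nrb_set,
            "stage_set": stage_set, "de_genes": de_genes, "beta": beta,
            "tom_net": tom_net, "mr": mr, "pair_hits": pair_hits,
            "edges": edges, "kept": kept}


def grn_benchmark(seed: int, **config_kwargs) -> GRNBenchmark:
    """End-to-end planted TF→target recovery on one simulated study."""
    study = simulate_study(SimulationConfig(seed=seed, **config_kwargs))
    res = analyse_study(study)
    planted = {tuple(sorted(p)) for p in study.ledger.planted_pairs()}
    retained = {(e.gene_a, e.gene_b) for e in res["kept"]}
    recovery = len(planted & retained) / len(planted) if planted else float("nan")
    spurious = len(retained - planted) / len(retained) if retained else 0.0
    return GRNBenchmark(seed, res["beta"], len(res["de_genes"]), len(planted),
                        len(retained), recovery, spurious)
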