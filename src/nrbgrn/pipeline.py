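"""End-to-end pipeline orchestration with a flat config and a run manifest.

Stages: quantify → differential expression → cohorts → co-expression network
→ promoter scan → GRN assembly, either on user-supplied inputs (counts or
coverage TSV, genome FASTA, TSS BED/GFF3, JASPAR PWMs, TF table) or in
synthetic mode, where the generator first writes a complete planted-truth
dataset.  Every output table carries a header comment with the resolved
parameters, and a JSON manifest records parameters and output digests.
Reruns with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cohorts as cohorts_mod
from . import de as de_mod
from . import grn as grn_mod
from . import motifs as motifs_mod
from . import network as net_mod
from . import quantify as quant_mod
from . import simulate as sim_mod
from .expression import read_matrix, write_lengths, write_matrix, write_meta

logger = logging.getLogger("nrbgrn")

__version__ = "0.1.0"


class StageError(RuntimeError):
    def __init__(self, stage: str, code: str, message: str):
        super().__init__(f"[{stage}:{code}] {message}")
        self.stage, self.code = stage, code


@dataclass
class PipelineConfig:
    """Flat, typed pipeline parameters; defaults are the published values."""

    synthetic: bool = True
    # input paths (real mode)
    counts: str | None = None
    coverage: str | None = None
    meta: str | None = None
    lengths: str | None = None
    genome: str | None = None
    tss: str | None = None
    pwms: str | None = None
    tf_table: str | None = None
    # stage parameters
    read_length: int = 151
    tpm_floor: float = 5.0
    fc: float = 5.0
    alpha: float = 0.05
    k_max: int = 10
    powers: tuple[int, ...] = tuple(range(1, 21))
    target_r2: float = 0.9
    rel_threshold: float = 0.85
    min_weight: float = 0.1
    min_mr: float = 0.98
    promoter_window: int = 1000
    seed: int = 0
    # synthetic generator sizes (used only when synthetic=True)
    n_genes: int = 2000
    n_stages: int = 15
    n_reps: int = 3
    n_modules: int = 4
    module_size: int = 5
    n_tfs: int = 4
    frac_de_tissue: float = 0.1
    frac_de_stage: float = 0.1
    de_fold: float = 8.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "powers" in doc:
            doc["powers"] = tuple(int(p) for p in doc["powers"])
        return cls(**doc)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["powers"] = list(self.powers)
        return d

    def sim_config(self) -> sim_mod.SimulationConfig:
        return sim_mod.SimulationConfig(
            n_genes=self.n_genes, n_stages=self.n_stages, n_reps=self.n_reps,
            n_modules=self.n_modules, module_size=self.module_size,
            n_tfs=self.n_tfs, frac_de_tissue=self.frac_de_tissue,
            frac_de_stage=self.frac_de_stage, de_fold=self.de_fold,
            promoter_len=self.promoter_window, seed=self.seed,
        )


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_table(df: pd.DataFrame, path: Path, params: dict, index: bool = False) -> None:
    with open(path, "w") as fh:
        for k, v in params.items():
            fh.write(f"# {k}={v}\n")
        df.to_csv(fh, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> dict:
    """Execute all stages; returns (and writes) the run manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    params = config.to_dict()
    manifest: dict = {"version": __version__, "parameters": params,
                      "stages": [], "outputs": {}}
    outputs: list[Path] = []

    def done(stage: str, *paths: Path) -> None:
        manifest["stages"].append(stage)
        outputs.extend(paths)
        logger.info("stage %s complete (%d output file(s))", stage, len(paths))

    # resolved-config snapshot next to the outputs
    cfg_path = outdir / "config.resolved.yaml"
    cfg_path.write_text(yaml.safe_dump(params, sort_keys=True))
    outputs.append(cfg_path)

    # -- stage 0: inputs ------------------------------------------------------
    ledger = None
    if config.synthetic:
        study = sim_mod.simulate_study(config.sim_config())
        counts = study.counts
        genome_path = outdir / "genome.fa"
        tss_path = outdir / "tss.bed"
        pwm_path = outdir / "pwms.jaspar.txt"
        tf_path = outdir / "tf_table.tsv"
        truth_path = outdir / "truth.json"
        study.genome.write_fasta(genome_path)
        study.genome.write_bed(tss_path)
        motifs_mod.write_pwms(study.pwm_counts, pwm_path)
        _write_table(pd.DataFrame(sorted(study.tf_table.items()),
                                  columns=["gene_id", "pwm_id"]), tf_path, params={})
        study.ledger.to_json(truth_path)
        write_matrix(counts, outdir / "counts.tsv")
        write_meta(counts, outdir / "meta.tsv")
        write_lengths(counts.lengths, outdir / "lengths.tsv")
        ledger = study.ledger
        done("simulate", genome_path, tss_path, pwm_path, tf_path, truth_path,
             outdir / "counts.tsv", outdir / "meta.tsv", outdir / "lengths.tsv")
    else:
        try:
            if config.coverage is not None:
                cov = read_matrix(config.coverage, config.meta, "coverage", config.lengths)
                counts = quant_mod.coverage_to_counts(cov, config.read_length)
            elif config.counts is not None:
                counts = read_matrix(config.counts, config.meta, "counts", config.lengths)
            else:
                raise StageError("quantify", "missing_input",
                                 "real mode needs a counts or coverage matrix")
        except (OSError, KeyError, ValueError) as exc:
            raise StageError("quantify", "input_error", str(exc)) from exc
        genome_path = Path(config.genome) if config.genome else None
        tss_path = Path(config.tss) if config.tss else None
        pwm_path = Path(config.pwms) if config.pwms else None
        tf_path = Path(config.tf_table) if config.tf_table else None

    # -- stage 1: quantify ----------------------------------------------------
    try:
        tpm = quant_mod.tpm_normalize(counts)
    except (ValueError, KeyError) as exc:
        raise StageError("quantify", "tpm_error", str(exc)) from exc
    write_matrix(tpm, outdir / "tpm.tsv", comments={"tpm_floor": config.tpm_floor})
    done("quantify", outdir / "tpm.tsv")

    # -- stage 2: differential expression --------------------------------------
    try:
        floor_genes = quant_mod.expression_floor(tpm, config.tpm_floor)
        tpm_f = tpm.subset_genes(floor_genes)
        nrb_set, nrb_table = de_mod.nrb_specific_genes(
            tpm_f, fc=config.fc, alpha=config.alpha, return_table=True)
        stage_set = de_mod.stagewise_degs(tpm_f, fc=config.fc, alpha=config.alpha)
        de_genes = de_mod.intersect_deg_sets(nrb_set, stage_set)
    except ValueError as exc:
        raise StageError("de", "contrast_error", str(exc)) from exc
    _write_table(nrb_table.reset_index(), outdir / "de_nrb_vs_internode.tsv",
                 {"fc": config.fc, "alpha": config.alpha})
    (outdir / "deg_intersection.txt").write_text("".join(f"{g}\n" for g in sorted(de_genes)))
    done("de", outdir / "de_nrb_vs_internode.tsv", outdir / "deg_intersection.txt")
    if not de_genes:
        raise StageError("de", "empty_deg_set", "no genes pass both DE filters")

    # -- stage 3: cohorts -------------------------------------------------------
    try:
        profiles = cohorts_mod.stage_profiles(tpm_f, sorted(de_genes))
        k_max = min(config.k_max, max(3, len(profiles.values) - 1))
        k, wss = cohorts_mod.choose_k_wss(profiles, k_max=k_max, seed=config.seed,
                                          return_curve=True)
        assign = cohorts_mod.kmeans_cohorts(profiles, k, seed=config.seed)
    except (ValueError, KeyError) as exc:
        raise StageError("cohorts", "clustering_error", str(exc)) from exc
    _write_table(assign.labels.rename("cohort").to_frame().reset_index(names="gene"),
                 outdir / "cohorts.tsv", {"k": k, "seed": config.seed})
    _write_table(pd.DataFrame({"k": range(1, len(wss) + 1), "wss": wss}),
                 outdir / "wss_curve.tsv", {})
    done("cohorts", outdir / "cohorts.tsv", outdir / "wss_curve.tsv")

    # -- stage 4: co-expression network ----------------------------------------
    try:
        # the co-expression network spans NRB development only: the stage
        # series, not the internode controls
        nrb_samples = tpm_f.samples_where(tissue_class="NRB")
        log_expr = np.log2(tpm_f.values[nrb_samples] + 1.0)
        beta, sft = net_mod.pick_soft_threshold(log_expr, config.powers,
                                                config.target_r2, return_table=True)
        adj = net_mod.pearson_adjacency(log_expr, beta)
        tom_net = net_mod.tom(adj)
        mr = net_mod.mutual_rank(tom_net, sorted(de_genes))
        edge_table = net_mod.network_edge_table(tom_net, mr)
    except (ValueError, KeyError) as exc:
        raise StageError("network", "network_error", str(exc)) from exc
    _write_table(sft, outdir / "soft_threshold.tsv", {"selected_power": beta})
    _write_table(edge_table, outdir / "network_edges.tsv",
                 {"beta": beta, "target_r2": config.target_r2})
    done("network", outdir / "soft_threshold.tsv", outdir / "network_edges.tsv")

    # -- stage 5: promoter scan -------------------------------------------------
    if genome_path is None or tss_path is None or pwm_path is None or tf_path is None:
        raise StageError("scan", "missing_input",
                         "genome, tss, pwms and tf_table are required for the scan stage")
    try:
        tss_table = motifs_mod.read_tss_table(tss_path)
        promoters = motifs_mod.extract_promoters(genome_path, tss_table,
                                                 window=config.promoter_window)
        motif_lib = motifs_mod.read_pwms(pwm_path)
        tf_df = pd.read_csv(tf_path, sep="\t", comment="#")
        tf_map = dict(zip(tf_df["gene_id"].astype(str), tf_df["pwm_id"].astype(str)))
        # only promoters of DE genes matter downstream; scanning them all is
        # supported but wasteful
        scan_proms = {g: p for g, p in promoters.items() if g in de_genes}
        pair_hits = motifs_mod.tf_target_map(tf_map, scan_proms, motif_lib,
                                             config.rel_threshold)
    except (OSError, KeyError, ValueError) as exc:
        raise StageError("scan", "scan_error", str(exc)) from exc
    _write_table(motifs_mod.hits_table(pair_hits), outdir / "motif_hits.tsv",
                 {"rel_threshold": config.rel_threshold})
    done("scan", outdir / "motif_hits.tsv")

    # -- stage 6: GRN assembly ----------------------------------------------------
    try:
        edges = grn_mod.build_grn(tom_net, mr, de_genes, pair_hits)
        kept = grn_mod.threshold_network(edges, config.min_weight, config.min_mr)
    except (KeyError, ValueError) as exc:
        raise StageError("grn", "assembly_error", str(exc)) from exc
    _write_table(grn_mod.edges_to_table(kept), outdir / "grn_edges.tsv",
                 {"min_weight": config.min_weight, "min_mr": config.min_mr})
    grn_mod.to_graphml(kept, outdir / "grn.graphml")
    done("grn", outdir / "grn_edges.tsv", outdir / "grn.graphml")

    manifest["outputs"] = {p.name: _sha256(p) for p in sorted(set(outputs))}
    manifest["n_de_genes"] = len(de_genes)
    manifest["selected_power"] = beta
    manifest["cohort_k"] = k
    manifest["n_edges_pruned"] = len(edges)
    manifest["n_edges_retained"] = len(kept)
    if ledger is not None:
        planted = {(a, b) for a, b in ledger.planted_pairs()}
        retained_pairs = {(e.gene_a, e.gene_b) for e in kept}
        canon = {tuple(sorted(p)) for p in planted}
        manifest["planted_pairs"] = len(planted)
        manifest["planted_pairs_retained"] = len(canon & retained_pairs)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest
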