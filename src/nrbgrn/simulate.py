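"""Synthetic data with planted ground truth for the whole pipeline.

The generator emulates the study design the pipeline expects: a nodal-root-bud
(NRB) developmental series of ~15 phytomer stages × 3 replicates of
negative-binomial RNA-seq counts, plus internode rind control samples; planted
tissue-specific and stage-varying differential expression at a known fold;
small TF-centred co-expression regulons driven by shared smooth latent stage
curves; and 1 kb promoters on both strands of synthetic contigs with PWM
consensus motifs embedded for designated TF→target pairs.

Regulons are star-shaped: the TF carries the module's latent stage curve and
each target adds a small individual smooth deviation, so targets correlate
more strongly with their TF than with each other.  This makes the planted
TF→target pairs mutually top-ranked partners — the regime the mutual-rank
retention rule (> 0.98) can recover in principle.

Planted tissue effects multiply a fixed reference composition, so the
class-mean count ratio of a planted gene equals ``de_fold`` exactly while
total library mass is allowed to differ between tissue classes (as it does in
real libraries).

Everything is a deterministic function of ``SimulationConfig.seed``.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline

from .expression import ExpressionMatrix, INTERNODE, NRB
from .motifs import MotifModel, revcomp

logger = logging.getLogger(__name__)

#: amplitude of each target's individual smooth deviation from its module curve
TARGET_DEVIATION = 0.15
#: log-sd of per-sample library-size factors
LIB_SIZE_LOG_SD = 0.08
#: nominal replicate noise sd in log space, used to scale background loadings
BG_NOISE_SD = 0.18
GENES_PER_CONTIG = 20
GENE_BODY_LEN = 30
CONTIG_GAP = 50


@dataclass
class SimulationConfig:
    """Parameters of the synthetic study.

    Defaults mirror the emulated design: 15 phytomer stages (7–21) × 3
    replicates plus 5 internode control groups; 4 TF-centred regulons of 5
    genes; 10% tissue-DE and 10% stage-DE genes planted at 8-fold.
    """

    n_genes: int = 2000
    n_stages: int = 15
    n_reps: int = 3
    n_modules: int = 4
    module_size: int = 5
    n_tfs: int = 4
    frac_de_tissue: float = 0.1
    frac_de_stage: float = 0.1
    de_fold: float = 8.0
    nb_dispersion: float = 0.02
    lib_size_mean: float = 2e6
    promoter_len: int = 1000
    motif_plant_rate: float = 0.75
    seed: int = 0
    n_controls: int = 5
    first_stage: int = 7
    n_bg_factors: int = 6
    bg_max_cor: float = 0.95
    background: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)

    def __post_init__(self):
        for name in ("n_genes", "n_stages", "n_reps", "n_modules", "module_size",
                     "n_tfs", "nb_dispersion", "lib_size_mean", "promoter_len",
                     "n_controls"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("frac_de_tissue", "frac_de_stage", "motif_plant_rate"):
            if not (0 <= getattr(self, name) <= 1):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.de_fold <= 1:
            raise ValueError("de_fold must exceed 1")
        if self.de_fold <= 5:
            warnings.warn("de_fold ≤ 5: planted genes cannot clear the 5-fold filter")
        if self.n_modules * self.module_size > self.n_genes:
            raise ValueError("n_modules × module_size exceeds n_genes")
        if self.n_tfs > self.n_modules:
            raise ValueError("each TF anchors one module: n_tfs must be ≤ n_modules")
        if abs(sum(self.background) - 1.0) > 1e-9:
            raise ValueError("background probabilities must sum to 1")

    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:05d}" for i in range(self.n_genes)]


@dataclass
class TruthLedger:
    """Planted ground truth: modules, DE sets, TF→target motif placements."""

    module_of: dict[str, int] = field(default_factory=dict)
    de_tissue: set[str] = field(default_factory=set)
    de_stage: set[str] = field(default_factory=set)
    tfs: list[str] = field(default_factory=list)
    tf_pwm: dict[str, str] = field(default_factory=dict)
    # (tf, target) → list of (offset, strand) placements in the target promoter
    tf_targets: dict[tuple[str, str], list[tuple[int, str]]] = field(default_factory=dict)

    def planted_pairs(self) -> set[tuple[str, str]]:
        return set(self.tf_targets)

    def to_json(self, path: str | Path) -> None:
        doc = {
            "module_of": self.module_of,
            "de_tissue": sorted(self.de_tissue),
            "de_stage": sorted(self.de_stage),
            "tfs": self.tfs,
            "tf_pwm": self.tf_pwm,
            "tf_targets": [
                {"tf": tf, "target": tgt,
                 "sites": [{"offset": o, "strand": s} for o, s in sites]}
                for (tf, tgt), sites in sorted(self.tf_targets.items())
            ],
        }
        with open(path, "w") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthLedger":
        with open(path) as fh:
            doc = json.load(fh)
        return cls(
            module_of={g: int(m) for g, m in doc["module_of"].items()},
            de_tissue=set(doc["de_tissue"]),
            de_stage=set(doc["de_stage"]),
            tfs=list(doc["tfs"]),
            tf_pwm=dict(doc["tf_pwm"]),
            tf_targets={(e["tf"], e["target"]): [(s["offset"], s["strand"]) for s in e["sites"]]
                        for e in doc["tf_targets"]},
        )


# -- latent stage curves -------------------------------------------------------


def stage_templates(n: int, n_stages: int) -> np.ndarray:
    """n distinct smooth stage templates on [0, 1], each scaled to range [0, 1].

    The first four echo the canonical cohort shapes — declining, early-
    peaking, late-peaking, rising — shaped so that no pair is strongly
    (anti-)correlated: an unsigned co-expression network cannot tell apart
    perfectly anticorrelated trajectories, so e.g. a linear rise and a linear
    decline would collapse into one module.  Further templates are Gaussian
    bumps with evenly spaced centres.
    """
    s = np.linspace(0.0, 1.0, n_stages)
    shapes = [np.exp(-((s / 0.30) ** 2)),
              np.exp(-(((s - 0.38) / 0.16) ** 2)),
              np.exp(-(((s - 0.68) / 0.16) ** 2)),
              np.exp(-((((1.0 - s) / 0.30) ** 2)))]
    for i in range(4, n):
        c = 0.1 + 0.8 * (i - 4) / max(n - 4, 1)
        shapes.append(np.exp(-(((s - c) / 0.15) ** 2)))
    out = np.array(shapes[:n])
    lo, hi = out.min(axis=1, keepdims=True), out.max(axis=1, keepdims=True)
    return (out - lo) / (hi - lo)


def _smooth_noise(rng: np.random.Generator, n_stages: int, n_knots: int = 5) -> np.ndarray:
    """A random smooth curve (cubic spline through random knots), sd ≈ 1."""
    x = np.linspace(0.0, 1.0, n_knots)
    y = rng.normal(size=n_knots)
    curve = CubicSpline(x, y)(np.linspace(0.0, 1.0, n_stages))
    sd = curve.std()
    return curve / sd if sd > 0 else curve


def _unit_range(curve: np.ndarray) -> np.ndarray:
    lo, hi = curve.min(), curve.max()
    if hi == lo:
        return np.zeros_like(curve)
    return (curve - lo) / (hi - lo)


# -- counts --------------------------------------------------------------------


def _sample_frame(config: SimulationConfig) -> pd.DataFrame:
    rows = []
    stages = range(config.first_stage, config.first_stage + config.n_stages)
    for stage in stages:
        for rep in range(1, config.n_reps + 1):
            rows.append((f"NRB_p{stage:02d}_r{rep}", stage, NRB, rep))
    # internode controls at evenly spread phytomer labels
    ctrl_stages = np.unique(np.linspace(config.first_stage - 1,
                                        config.first_stage + config.n_stages - 1,
                                        config.n_controls).round().astype(int))
    for stage in ctrl_stages:
        for rep in range(1, config.n_reps + 1):
            rows.append((f"INT_p{stage:02d}_r{rep}", stage, INTERNODE, rep))
    meta = pd.DataFrame(rows, columns=["sample_id", "stage", "tissue_class", "replicate"])
    meta["stage"] = meta["stage"].astype("Int64")
    return meta


def simulate_counts(config: SimulationConfig) -> tuple[ExpressionMatrix, TruthLedger]:
    """Negative-binomial counts with planted modules and DE effects.

    Returns the count matrix (with sample metadata and transcript lengths
    attached) and the truth ledger.  ``ledger.tf_targets`` is filled later by
    :func:`simulate_promoters`.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(1,)))
    genes = config.gene_ids
    n = config.n_genes
    n_module_genes = config.n_modules * config.module_size

    ledger = TruthLedger()
    for m in range(config.n_modules):
        for j in range(config.module_size):
            ledger.module_of[genes[m * config.module_size + j]] = m
    ledger.tfs = [genes[m * config.module_size] for m in range(config.n_tfs)]

    # planted gene rosters.  Both sets draw from the same ordered candidate
    # list (module genes first, then singletons), so tissue-DE and stage-DE
    # genes overlap heavily — NRB developmental genes are both NRB-enriched
    # and stage-dynamic, and the downstream intersection is only meaningful
    # when the overlap is substantial.
    n_ds = int(round(config.frac_de_stage * n))
    n_dt = int(round(config.frac_de_tissue * n))
    n_planted = max(n_ds, n_dt)
    candidates = list(range(min(n_module_genes, n_planted)))
    candidates += list(range(n_module_genes,
                             n_module_genes + max(0, n_planted - n_module_genes)))
    stage_idx = candidates[:n_ds]
    tissue_idx = candidates[:n_dt]
    ledger.de_stage = {genes[i] for i in stage_idx}
    ledger.de_tissue = {genes[i] for i in tissue_idx}

    # baseline relative abundances: heavy-tailed background; DE singletons
    # low-to-moderate (tissue-specific genes are not bulk housekeeping mass,
    # which keeps the planted fold change recoverable on the TPM scale after
    # per-sample renormalisation); regulon genes moderate-to-high so the
    # network stage has signal
    w = rng.lognormal(0.0, 1.4, size=n)
    module_rows = list(range(n_module_genes))
    singles = sorted(set(stage_idx) | set(tissue_idx) - set(module_rows))
    singles = [i for i in singles if i >= n_module_genes]
    w[singles] = rng.lognormal(-0.5, 0.5, size=len(singles))
    w[module_rows] = rng.lognormal(1.1, 0.4, size=n_module_genes)

    # latent stage curves (fold multipliers, arithmetic mean 1 across stages)
    templates = stage_templates(config.n_modules, config.n_stages)
    log_fold = np.log(config.de_fold)
    curves = np.ones((n, config.n_stages))
    for i in stage_idx:
        g = genes[i]
        if g in ledger.module_of:
            t = templates[ledger.module_of[g]]
            if g not in ledger.tfs:  # targets deviate slightly from the hub curve
                t = _unit_range(t + TARGET_DEVIATION * _smooth_noise(rng, config.n_stages))
        else:
            # singleton trajectories get more knots than the module curves:
            # independent stage-DE genes should not alias onto regulon curves
            t = _unit_range(_smooth_noise(rng, config.n_stages, n_knots=9))
        curve = np.exp(log_fold * t)
        curves[i] = curve / curve.mean()

    # background co-expression: genes outside the planted rosters share a
    # low-rank space of latent smooth stage factors, each gene loading in a
    # random direction with a broad (mostly-weak, few-strong) signal
    # fraction.  This reproduces the pervasive correlation and heavy-tailed
    # connectivity of real transcriptomes, which the scale-free
    # soft-threshold fit relies on; signal fractions stay below the regulon
    # correlations so background genes do not outrank planted partners.
    bg_rows = np.array(sorted(set(range(n)) - set(stage_idx)), dtype=int)
    if bg_rows.size and config.n_bg_factors > 0:
        factors = np.array([_smooth_noise(rng, config.n_stages)
                            for _ in range(config.n_bg_factors)])
        factors -= factors.mean(axis=1, keepdims=True)
        factors /= factors.std(axis=1, keepdims=True)
        directions = rng.normal(size=(bg_rows.size, config.n_bg_factors))
        directions /= np.linalg.norm(directions, axis=1, keepdims=True)
        r = config.bg_max_cor * rng.beta(1.2, 2.5, size=bg_rows.size)
        lam = BG_NOISE_SD * r / np.sqrt(1.0 - r**2)
        bg_curves = np.exp(lam[:, None] * (directions @ factors))
        curves[bg_rows] = bg_curves / bg_curves.mean(axis=1, keepdims=True)

    meta = _sample_frame(config)
    is_nrb = (meta["tissue_class"] == NRB).to_numpy()
    stage_pos = (meta["stage"].to_numpy(dtype=float) - config.first_stage).astype(int)

    tissue_fac = np.ones(n)
    tissue_fac[tissue_idx] = config.de_fold

    expected = np.empty((n, len(meta)))
    for j in range(len(meta)):
        if is_nrb[j]:
            expected[:, j] = w * curves[:, stage_pos[j]] * tissue_fac
        else:
            expected[:, j] = w
    # fixed reference composition: planted ratios are exact in count space
    expected /= w.sum()

    lib = config.lib_size_mean * rng.lognormal(0.0, LIB_SIZE_LOG_SD, size=len(meta))
    mu = expected * lib
    shape = 1.0 / config.nb_dispersion
    lam = rng.gamma(shape, mu * config.nb_dispersion)
    counts = rng.poisson(lam).astype(float)

    lengths = pd.Series(
        np.clip(np.exp(rng.normal(np.log(1500.0), 0.45, size=n)), 300, 8000).round(),
        index=genes, name="length",
    )
    values = pd.DataFrame(counts, index=genes, columns=meta["sample_id"])
    expr = ExpressionMatrix(values, "counts", meta, lengths)
    return expr, ledger


# -- PWMs ----------------------------------------------------------------------


def generate_pwm_counts(n: int, seed: int, length_range: tuple[int, int] = (9, 13),
                        consensus_count: int = 85, other_count: int = 5,
                        ) -> dict[str, np.ndarray]:
    """Sharp JASPAR-style count matrices (4 × L) with a unique consensus."""
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(3,)))
    out: dict[str, np.ndarray] = {}
    for i in range(n):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        counts = np.full((4, length), other_count, dtype=int)
        consensus = rng.integers(0, 4, size=length)
        counts[consensus, np.arange(length)] = consensus_count
        out[f"PWM{i:03d}"] = counts
    return out


def pwms_from_counts(count_matrices: dict[str, np.ndarray],
                     background=(0.25, 0.25, 0.25, 0.25)) -> dict[str, MotifModel]:
    return {pid: MotifModel(pid, np.asarray(c, float) / np.asarray(c, float).sum(axis=0),
                            tuple(background))
            for pid, c in count_matrices.items()}


# -- promoters and genome ------------------------------------------------------


@dataclass
class SyntheticGenome:
    contigs: dict[str, str]
    tss_table: pd.DataFrame            # contig, tss, gene, strand
    promoters: dict[str, str]          # gene → promoter sequence (strand-corrected)

    def write_fasta(self, path: str | Path, width: int = 80) -> None:
        with open(path, "w") as fh:
            for name in self.contigs:
                fh.write(f">{name}\n")
                seq = self.contigs[name]
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")

    def write_bed(self, path: str | Path) -> None:
        bed = pd.DataFrame({
            "contig": self.tss_table["contig"],
            "start": self.tss_table["tss"],
            "end": self.tss_table["tss"] + 1,
            "gene": self.tss_table["gene"],
            "score": 0,
            "strand": self.tss_table["strand"],
        })
        bed.to_csv(path, sep="\t", header=False, index=False)


def simulate_promoters(genes: list[str], tf_list: list[str],
                       pwms: dict[str, MotifModel], config: SimulationConfig,
                       ledger: TruthLedger | None = None) -> SyntheticGenome:
    """Synthetic contigs with strand-alternating genes and planted motifs.

    Each TF is mapped to one PWM (in ``tf_list`` order); for every module
    mate of a TF, its PWM consensus is embedded in the mate's promoter with
    probability ``motif_plant_rate``, at a recorded offset and strand.  The
    ledger (if given) is updated in place with ``tf_pwm`` and ``tf_targets``.
    """
    if len(tf_list) > len(pwms):
        raise ValueError("need at least one PWM per TF")
    longest = max(m.length for m in pwms.values())
    if config.promoter_len < longest:
        raise ValueError("promoter_len shorter than the longest PWM")
    rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(2,)))
    pwm_ids = sorted(pwms)
    tf_pwm = {tf: pwm_ids[i] for i, tf in enumerate(tf_list)}

    base_arr = np.frombuffer("ACGT".encode(), dtype="S1")
    probs = np.asarray(config.background)

    def random_seq(k: int) -> np.ndarray:
        return rng.choice(base_arr, size=k, p=probs)

    # promoter sequences with planted consensus sites
    promoters: dict[str, np.ndarray] = {
        g: random_seq(config.promoter_len) for g in genes
    }
    if ledger is not None:
        ledger.tf_pwm.update(tf_pwm)
        for tf in tf_list:
            module = ledger.module_of.get(tf)
            if module is None:
                continue
            motif = pwms[tf_pwm[tf]]
            cons = motif.consensus
            mates = [g for g, m in ledger.module_of.items() if m == module and g != tf]
            for mate in mates:
                if rng.random() >= config.motif_plant_rate:
                    continue
                offset = int(rng.integers(0, config.promoter_len - motif.length + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                site = cons if strand == "+" else revcomp(cons)
                promoters[mate][offset:offset + motif.length] = \
                    np.frombuffer(site.encode(), dtype="S1")
                ledger.tf_targets.setdefault((tf, mate), []).append((offset, strand))

    # lay genes onto contigs, alternating strands
    contigs: dict[str, str] = {}
    rows = []
    for c0 in range(0, len(genes), GENES_PER_CONTIG):
        name = f"contig{c0 // GENES_PER_CONTIG:03d}"
        parts: list[np.ndarray] = []
        cursor = 0
        for k, g in enumerate(genes[c0:c0 + GENES_PER_CONTIG]):
            gap = random_seq(CONTIG_GAP)
            parts.append(gap)
            cursor += CONTIG_GAP
            body = random_seq(GENE_BODY_LEN)
            prom = promoters[g]
            if k % 2 == 0:       # plus strand: [TSS−P, TSS) then body
                parts.append(prom)
                tss = cursor + config.promoter_len
                parts.append(body)
                strand = "+"
            else:                # minus strand: body, TSS, then (TSS, TSS+P] rc'd
                parts.append(body)
                tss = cursor + GENE_BODY_LEN - 1
                rc = np.frombuffer(revcomp(prom.tobytes().decode()).encode(), dtype="S1")
                parts.append(rc)
                strand = "-"
            cursor += config.promoter_len + GENE_BODY_LEN
            rows.append((name, tss, g, strand))
        parts.append(random_seq(CONTIG_GAP))
        contigs[name] = b"".join(p.tobytes() for p in parts).decode()

    tss_table = pd.DataFrame(rows, columns=["contig", "tss", "gene", "strand"])
    prom_str = {g: p.tobytes().decode() for g, p in promoters.items()}
    return SyntheticGenome(contigs, tss_table, prom_str)


# -- one-call bundle -----------------------------------------------------------


@dataclass
class SimulatedStudy:
    config: SimulationConfig
    counts: ExpressionMatrix
    ledger: TruthLedger
    genome: SyntheticGenome
    pwms: dict[str, MotifModel]
    pwm_counts: dict[str, np.ndarray]
    tf_table: dict[str, str]


def simulate_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate counts, promoters, PWMs, and the truth ledger in one call."""
    counts, ledger = simulate_counts(config)
    pwm_counts = generate_pwm_counts(max(config.n_tfs, 1), config.seed)
    pwms = pwms_from_counts(pwm_counts, config.background)
    genome = simulate_promoters(config.gene_ids, ledger.tfs, pwms, config, ledger)
    return SimulatedStudy(config, counts, ledger, genome, pwms, pwm_counts,
                          dict(ledger.tf_pwm))


# -- profile-only simulation (cohort clustering benchmarks) --------------------


def simulate_profile_set(n_genes: int, n_stages: int, n_clusters: int,
                         noise_sd: float, seed: int) -> tuple[pd.DataFrame, pd.Series]:
    """Gene × stage profiles drawn from separated templates plus iid noise.

    Templates are z-scaled and then orthogonalised (Gram–Schmidt) so the
    cluster centroids are mutually equidistant: for equidistant, equally
    sized clusters the within-sum-of-squares curve has its maximum second
    difference exactly at the true k, which is what an elbow benchmark
    should provide.  ``noise_sd`` is in template-sd units.  Returns the
    profile matrix and true labels (1-based).
    """
    rng = np.random.default_rng(seed)
    templates = stage_templates(n_clusters, n_stages)
    templates = templates - templates.mean(axis=1, keepdims=True)
    q, _ = np.linalg.qr(templates.T)           # orthogonal smooth combinations
    templates = q.T * np.sqrt(n_stages - 1)    # back to sd ≈ 1 rows, mean ≈ 0
    labels = np.repeat(np.arange(n_clusters), int(np.ceil(n_genes / n_clusters)))[:n_genes]
    x = templates[labels] + rng.normal(0.0, noise_sd, size=(n_genes, n_stages))
    genes = [f"g{i:05d}" for i in range(n_genes)]
    return (pd.DataFrame(x, index=genes, columns=range(n_stages)),
            pd.Series(labels + 1, index=genes, name="cluster"))
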