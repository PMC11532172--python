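"""Promoter extraction and PWM scanning for TF→target binding prediction.

Promoters span 1 kb upstream of the transcription start site, strand-aware:
for a plus-strand gene the window is [TSS−1000, TSS) on the forward strand;
for a minus-strand gene it is (TSS, TSS+1000] reverse-complemented.  Windows
are clipped (and flagged) at contig edges.  Coordinates are 0-based
half-open internally; BED6 is read natively and GFF3 is converted.

PWMs are scored by log-odds against a background model with pseudocount
regularisation; a hit's relative score rescales the log-odds between the
minimum and maximum attainable for that matrix, so the consensus sequence
always scores exactly 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import motifs as bio_motifs
from pyfaidx import Fasta

logger = logging.getLogger(__name__)

BASES = "ACGT"
_BASE_INDEX = {b: i for i, b in enumerate(BASES)}
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_WINDOW = 1000
DEFAULT_REL_THRESHOLD = 0.85
DEFAULT_PSEUDOCOUNT = 0.1
UNIFORM_BG = (0.25, 0.25, 0.25, 0.25)


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


# -- PWM model -----------------------------------------------------------------


@dataclass
class MotifModel:
    """A position probability matrix with background and pseudocount.

    ``matrix`` is 4 × L (rows A, C, G, T), columns summing to 1.
    """

    pwm_id: str
    matrix: np.ndarray
    background: tuple[float, float, float, float] = UNIFORM_BG
    pseudocount: float = DEFAULT_PSEUDOCOUNT

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.shape[0] != 4:
            raise ValueError("PWM matrix must have 4 rows (A, C, G, T)")
        if self.matrix.shape[1] < 4:
            raise ValueError("PWM must have ≥4 columns")
        colsum = self.matrix.sum(axis=0)
        if not np.allclose(colsum, 1.0, atol=1e-6):
            raise ValueError(f"PWM {self.pwm_id}: columns must sum to 1")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def score_matrix(self) -> np.ndarray:
        """4 × L per-base log2-odds with pseudocount regularisation."""
        bg = np.asarray(self.background, dtype=float)[:, None]
        p = (self.matrix + self.pseudocount * bg) / (1.0 + self.pseudocount)
        return np.log2(p / bg)

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    def score_bounds(self) -> tuple[float, float]:
        s = self.score_matrix
        return float(s.min(axis=0).sum()), float(s.max(axis=0).sum())

    def reverse_complement(self) -> "MotifModel":
        return MotifModel(self.pwm_id, self.matrix[::-1, ::-1],
                          self.background, self.pseudocount)


def read_pwms(path: str | Path, background=UNIFORM_BG,
              pseudocount: float = DEFAULT_PSEUDOCOUNT) -> dict[str, MotifModel]:
    """Read a JASPAR-style PWM library; counts are column-normalised."""
    with open(path) as fh:
        records = bio_motifs.parse(fh, "jaspar")
    out: dict[str, MotifModel] = {}
    for rec in records:
        counts = np.array([rec.counts[b] for b in BASES], dtype=float)
        out[rec.matrix_id] = MotifModel(rec.matrix_id, counts / counts.sum(axis=0),
                                        background, pseudocount)
    return out


def write_pwms(count_matrices: dict[str, np.ndarray], path: str | Path) -> None:
    """Write integer count matrices in JASPAR text format."""
    with open(path, "w") as fh:
        for pwm_id, counts in count_matrices.items():
            counts = np.asarray(counts)
            fh.write(f">{pwm_id} {pwm_id}\n")
            for b, row in zip(BASES, counts):
                cells = " ".join(f"{v:6.0f}" for v in row)
                fh.write(f"{b} [ {cells} ]\n")


# -- promoter extraction -------------------------------------------------------


@dataclass
class Promoter:
    gene: str
    sequence: str
    contig: str
    start: int                 # 0-based half-open genomic interval
    end: int
    strand: str
    clipped: bool = False


PromoterSet = dict[str, Promoter]


def read_tss_table(path: str | Path) -> pd.DataFrame:
    """TSS positions from BED6 or GFF3 → columns contig, tss, gene, strand.

    BED is 0-based half-open (TSS = start); GFF3 rows are 1-based inclusive
    (TSS = start−1 for + features, end−1 for −).
    """
    path = Path(path)
    if path.suffix.lower() in {".gff", ".gff3"}:
        gff = pd.read_csv(path, sep="\t", comment="#", header=None,
                          names=["contig", "source", "type", "start", "end",
                                 "score", "strand", "frame", "attr"])
        gene = gff["attr"].str.extract(r"ID=([^;]+)")[0]
        tss = np.where(gff["strand"] == "+", gff["start"] - 1, gff["end"] - 1)
        return pd.DataFrame({"contig": gff["contig"], "tss": tss,
                             "gene": gene, "strand": gff["strand"]})
    bed = pd.read_csv(path, sep="\t", comment="#", header=None,
                      names=["contig", "start", "end", "gene", "score", "strand"])
    return pd.DataFrame({"contig": bed["contig"], "tss": bed["start"],
                         "gene": bed["gene"], "strand": bed["strand"]})


def extract_promoters(genome: str | Path | Fasta, tss_table: pd.DataFrame,
                      window: int = DEFAULT_WINDOW) -> PromoterSet:
    """Strand-aware promoter windows upstream of each TSS."""
    fasta = genome if isinstance(genome, Fasta) else Fasta(str(genome))
    out: PromoterSet = {}
    for row in tss_table.itertuples(index=False):
        if row.contig not in fasta:
            raise KeyError(f"TSS contig {row.contig!r} not in genome FASTA")
        contig_len = len(fasta[row.contig])
        tss = int(row.tss)
        if not (0 <= tss < contig_len):
            raise ValueError(f"TSS {tss} of gene {row.gene!r} off contig {row.contig!r}")
        if row.strand == "+":
            start, end = max(0, tss - window), tss
            seq = fasta[row.contig][start:end].seq.upper()
        elif row.strand == "-":
            start, end = tss + 1, min(contig_len, tss + 1 + window)
            seq = revcomp(fasta[row.contig][start:end].seq.upper())
        else:
            raise ValueError(f"unknown strand {row.strand!r} for gene {row.gene!r}")
        clipped = (end - start) < window
        if clipped:
            logger.warning("promoter of %s clipped to %d bp at contig edge",
                           row.gene, end - start)
        out[str(row.gene)] = Promoter(str(row.gene), seq, str(row.contig),
                                      start, end, str(row.strand), clipped)
    return out


# -- scanning ------------------------------------------------------------------


@dataclass(frozen=True)
class MotifHit:
    gene: str
    pwm_id: str
    offset: int                # 0-based within the promoter sequence
    strand: str                # '+' match to the given sequence, '-' to its rc
    log_odds: float
    rel_score: float


def _encode(seq: str) -> np.ndarray:
    """ACGT → 0..3, N and other ambiguity codes → 4."""
    arr = np.full(len(seq), 4, dtype=np.int8)
    for base, code in _BASE_INDEX.items():
        arr[np.frombuffer(seq.encode(), dtype=np.uint8) == ord(base)] = code
    return arr


def pwm_score(window_seq: str, motif: MotifModel) -> float:
    """Log-odds of a single window exactly the motif's length.

    Windows containing N score −inf; any other non-ACGT character is an
    error.
    """
    if len(window_seq) != motif.length:
        raise ValueError("window length must equal motif length")
    window_seq = window_seq.upper()
    invalid = set(window_seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"invalid sequence characters: {sorted(invalid)}")
    if "N" in window_seq:
        return float("-inf")
    s = motif.score_matrix
    return float(sum(s[_BASE_INDEX[b], i] for i, b in enumerate(window_seq)))


def _scan_one_strand(codes: np.ndarray, score_matrix: np.ndarray) -> np.ndarray:
    """Log-odds at every offset; windows containing N get −inf."""
    length = score_matrix.shape[1]
    n_win = codes.size - length + 1
    if n_win <= 0:
        return np.empty(0)
    padded = np.vstack([score_matrix, np.full(length, -np.inf)])  # row 4 = N
    windows = np.lib.stride_tricks.sliding_window_view(codes, length)
    return padded[windows, np.arange(length)].sum(axis=1)


def scan_promoter(promoter: Promoter, motif: MotifModel,
                  rel_threshold: float = DEFAULT_REL_THRESHOLD) -> list[MotifHit]:
    """All hits of *motif* on both strands of a promoter.

    Hits are offsets (in promoter coordinates) where the relative score
    meets *rel_threshold*; minus-strand hits are matches of the
    reverse-complement motif at that offset.  Sorted by offset then strand.
    """
    if not (0 < rel_threshold <= 1):
        raise ValueError("rel_threshold must lie in (0, 1]")
    seq = promoter.sequence.upper()
    invalid = set(seq) - set("ACGTN")
    if invalid:
        raise ValueError(f"invalid sequence characters: {sorted(invalid)}")
    if len(seq) < motif.length:
        return []
    codes = _encode(seq)
    lo, hi = motif.score_bounds()
    span = hi - lo
    hits: list[MotifHit] = []
    for strand, m in (("+", motif), ("-", motif.reverse_complement())):
        scores = _scan_one_strand(codes, m.score_matrix)
        rel = (scores - lo) / span
        for off in np.nonzero(rel >= rel_threshold - 1e-12)[0]:
            hits.append(MotifHit(promoter.gene, motif.pwm_id, int(off), strand,
                                 float(scores[off]), float(min(rel[off], 1.0))))
    hits.sort(key=lambda h: (h.offset, h.strand))
    return hits


def tf_target_map(tf_table: dict[str, str], promoters: PromoterSet,
                  motif_library: dict[str, MotifModel],
                  rel_threshold: float = DEFAULT_REL_THRESHOLD,
                  ) -> dict[tuple[str, str], list[MotifHit]]:
    """(tf, target) pairs whose promoter scan yields ≥1 hit of the TF's PWM.

    Self pairs (tf, tf) are included and can be recognised by equal
    elements.  TFs whose PWM is missing from the library are skipped with a
    warning.
    """
    out: dict[tuple[str, str], list[MotifHit]] = {}
    for tf, pwm_id in tf_table.items():
        motif = motif_library.get(pwm_id)
        if motif is None:
            logger.warning("TF %s: PWM %s not in library; skipped", tf, pwm_id)
            continue
        for gene, prom in promoters.items():
            hits = scan_promoter(prom, motif, rel_threshold)
            if hits:
                out[(tf, gene)] = hits
    return out


def hits_table(pair_hits: dict[tuple[str, str], list[MotifHit]]) -> pd.DataFrame:
    rows = [
        {"tf": tf, "gene": gene, "pwm_id": h.pwm_id, "offset": h.offset,
         "strand": h.strand, "log_odds": h.log_odds, "rel_score": h.rel_score}
        for (tf, gene), hits in sorted(pair_hits.items())
        for h in hits
    ]
    return pd.DataFrame(rows, columns=["tf", "gene", "pwm_id", "offset",
                                       "strand", "log_odds", "rel_score"])
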