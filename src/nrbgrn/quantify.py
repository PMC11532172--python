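"""Coverage → counts → TPM quantification and expression filters.

Counts are recovered from per-transcript nucleotide coverage with
``reads = coverage · transcript_length / read_length`` (151 bp reads by
default), then TPM-normalised so each sample column sums to one million.
An expression floor (TPM > 5 in at least one sample) gates every downstream
stage, and a per-gene MAD statistic selects the most variable genes for
embedding-style visualisation.
"""

from __future__ import annotations

import logging

import numpy as np

from .expression import ExpressionMatrix

logger = logging.getLogger(__name__)

DEFAULT_READ_LENGTH = 151


def coverage_to_counts(coverage: ExpressionMatrix, read_length: int = DEFAULT_READ_LENGTH) -> ExpressionMatrix:
    """Convert nucleotide coverage to integer read counts.

    Each cell becomes ``coverage · length / read_length`` rounded half-up.
    ``coverage.lengths`` must provide a length for every gene.
    """
    if read_length <= 0:
        raise ValueError("read_length must be positive")
    if coverage.unit != "coverage":
        raise ValueError(f"expected a coverage matrix, got unit={coverage.unit!r}")
    if coverage.lengths is None:
        raise ValueError("transcript lengths are required for coverage conversion")
    missing = [g for g in coverage.genes if g not in coverage.lengths.index]
    if missing:
        raise KeyError(f"no transcript length for gene {missing[0]!r}")
    lengths = coverage.lengths.loc[coverage.genes]
    if (lengths <= 0).any():
        bad = lengths.index[lengths <= 0][0]
        raise ValueError(f"non-positive transcript length for gene {bad!r}")
    raw = coverage.values.mul(lengths, axis=0) / read_length
    counts = np.floor(raw + 0.5)  # round half-up, fixed for reproducibility
    return ExpressionMatrix(counts, "counts", coverage.meta.copy(), coverage.lengths)


def tpm_normalize(counts: ExpressionMatrix) -> ExpressionMatrix:
    """Length-normalise counts to transcripts-per-million.

    TPM_g = 1e6 · (count_g / length_g) / Σ_h (count_h / length_h), per sample.
    """
    if counts.unit != "counts":
        raise ValueError(f"expected a counts matrix, got unit={counts.unit!r}")
    if counts.lengths is None:
        raise ValueError("transcript lengths are required for TPM normalisation")
    lengths = counts.lengths.loc[counts.genes]
    rate = counts.values.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum.index[colsum == 0]
    if len(zero):
        raise ValueError(f"TPM undefined: sample {zero[0]!r} has all-zero counts")
    tpm = rate.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(tpm, "TPM", counts.meta.copy(), counts.lengths)


def expression_floor(tpm: ExpressionMatrix, threshold: float = 5.0,
                     scope: list[str] | None = None) -> list[str]:
    """Genes with TPM strictly above *threshold* in ≥1 sample of *scope*.

    The strict inequality matters at the boundary: a gene sitting exactly at
    the floor in every replicate is excluded.
    """
    if tpm.unit != "TPM":
        raise ValueError("expression_floor expects a TPM matrix")
    scope = list(scope) if scope is not None else tpm.sample_ids
    if not scope:
        raise ValueError("empty sample scope")
    sub = tpm.values[scope]
    keep = (sub > threshold).any(axis=1)
    return list(sub.index[keep])


def mad_top_genes(matrix: ExpressionMatrix, n: int) -> list[str]:
    """The *n* genes with the largest MAD of their z-scaled profiles.

    Each gene is scaled to mean 0 / sd 1 across samples before the median
    absolute deviation is taken, so the statistic ranks profile shape
    dispersion rather than raw expression magnitude.  Constant genes cannot
    be scaled; their MAD is taken on the unscaled values (which is 0) and a
    warning is logged.  Ties are broken by gene ID so the order is total.
    """
    if n > len(matrix.genes):
        raise ValueError(f"n={n} exceeds the number of genes ({len(matrix.genes)})")
    vals = matrix.values
    mu = vals.mean(axis=1)
    sd = vals.std(axis=1, ddof=1)
    constant = sd == 0
    if constant.any():
        logger.warning("%d constant gene(s); MAD computed on unscaled values", int(constant.sum()))
    scaled = vals.sub(mu, axis=0).div(sd.where(~constant, 1.0), axis=0)
    scaled[constant] = vals[constant]
    mad = (scaled.sub(scaled.median(axis=1), axis=0)).abs().median(axis=1)
    # mergesort is stable; pre-sorting the index lexicographically makes ties
    # break by gene ID
    order = mad.loc[sorted(mad.index)].sort_values(ascending=False, kind="mergesort")
    return list(order.index[:n])
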