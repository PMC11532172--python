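"""Promoter extraction, PWM scoring/scanning, and TF→target mapping."""

import numpy as np
import pytest

from nrbgrn.motifs import (MotifModel, Promoter, extract_promoters, pwm_score,
                           read_pwms, read_tss_table, revcomp, scan_promoter,
                           tf_target_map, write_pwms)
from nrbgrn.simulate import generate_pwm_counts

COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def _manual_revcomp(seq):
    return "".join(COMPLEMENT[b] for b in reversed(seq))


def _sharp_pwm(consensus, pwm_id="toy"):
    mat = np.full((4, len(consensus)), 0.05)
    for i, b in enumerate(consensus):
        mat["ACGT".index(b), i] = 0.85
    return MotifModel(pwm_id, mat)


# -- scoring --------------------------------------------------------------------


def test_consensus_scores_maximum():
    m = _sharp_pwm("ACGTAC")
    lo, hi = m.score_bounds()
    assert pwm_score(m.consensus, m) == pytest.approx(hi, abs=1e-12)


def test_uniform_pwm_scores_zero_everywhere():
    m = MotifModel("flat", np.full((4, 5), 0.25))
    assert pwm_score("ACGTA", m) == pytest.approx(0.0, abs=1e-12)
    assert pwm_score("TTTTT", m) == pytest.approx(0.0, abs=1e-12)


def test_score_is_sum_of_column_log_odds():
    mat = np.array([[0.7, 0.1, 0.1, 0.1],
                    [0.1, 0.6, 0.2, 0.1],
                    [0.1, 0.2, 0.6, 0.2],
                    [0.1, 0.1, 0.1, 0.6]])
    m = MotifModel("hand", mat, pseudocount=0.1)
    expected = sum(
        np.log2((mat["ACGT".index(b), i] + 0.1 * 0.25) / (1.1 * 0.25))
        for i, b in enumerate("ACGT")
    )
    assert pwm_score("ACGT", m) == pytest.approx(expected, abs=1e-12)


def test_window_with_n_scores_minus_infinity():
    m = _sharp_pwm("ACGTA")
    assert pwm_score("ACNTA", m) == float("-inf")
    with pytest.raises(ValueError, match="invalid"):
        pwm_score("ACXTA", m)


# -- scanning -------------------------------------------------------------------


def test_planted_consensus_found_exactly_at_threshold_one(rng):
    m = _sharp_pwm("ACGTACGTTA")
    flank = "".join(rng.choice(list("ACGT"), size=40))
    seq = flank + m.consensus + flank
    prom = Promoter("g", seq, "c", 0, len(seq), "+")
    hits = [h for h in scan_promoter(prom, m, rel_threshold=1.0)]
    assert any(h.offset == 40 and h.strand == "+" for h in hits)
    for h in hits:
        assert h.rel_score == pytest.approx(1.0)


def test_minus_strand_site_reported_at_its_offset():
    m = _sharp_pwm("AAACGTACGG")   # not reverse-palindromic
    seq = "T" * 20 + revcomp(m.consensus) + "T" * 20
    prom = Promoter("g", seq, "c", 0, len(seq), "+")
    hits = scan_promoter(prom, m, rel_threshold=1.0)
    assert [(h.offset, h.strand) for h in hits] == [(20, "-")]


def test_lower_threshold_grows_hit_set(rng):
    m = _sharp_pwm("ACGTACGT")
    seq = "".join(rng.choice(list("ACGT"), size=300))
    prom = Promoter("g", seq, "c", 0, 300, "+")
    strict = {(h.offset, h.strand) for h in scan_promoter(prom, m, 0.8)}
    loose = {(h.offset, h.strand) for h in scan_promoter(prom, m, 0.6)}
    assert strict <= loose


def test_all_n_promoter_has_no_hits():
    m = _sharp_pwm("ACGTA")
    prom = Promoter("g", "N" * 100, "c", 0, 100, "+")
    assert scan_promoter(prom, m, 0.5) == []


def test_short_promoter_returns_empty():
    m = _sharp_pwm("ACGTACGTA")
    prom = Promoter("g", "ACG", "c", 0, 3, "+")
    assert scan_promoter(prom, m, 0.5) == []


def test_rel_scores_bounded(rng):
    m = _sharp_pwm("ACGTTGCA")
    seq = "".join(rng.choice(list("ACGT"), size=500))
    prom = Promoter("g", seq, "c", 0, 500, "+")
    for h in scan_promoter(prom, m, 0.5):
        assert 0.0 <= h.rel_score <= 1.0


def test_strand_symmetry(rng):
    """Hits on a sequence map one-to-one onto its reverse complement with
    flipped strand and mirrored offset."""
    m = _sharp_pwm("ACGTACGTTA")
    seq = "".join(rng.choice(list("ACGT"), size=200)) + m.consensus + \
        "".join(rng.choice(list("ACGT"), size=50))
    fwd = scan_promoter(Promoter("g", seq, "c", 0, len(seq), "+"), m, 0.8)
    rev = scan_promoter(Promoter("g", _manual_revcomp(seq), "c", 0, len(seq), "+"), m, 0.8)
    flip = {"+": "-", "-": "+"}
    mapped = {(len(seq) - h.offset - m.length, flip[h.strand], round(h.log_odds, 9))
              for h in rev}
    assert {(h.offset, h.strand, round(h.log_odds, 9)) for h in fwd} == mapped


# -- promoter extraction ----------------------------------------------------------


def _write_fasta(tmp_path, contigs):
    path = tmp_path / "genome.fa"
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n{seq}\n")
    return path


def test_plus_strand_window_is_exact(tmp_path, rng):
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    fasta = _write_fasta(tmp_path, {"c1": seq})
    import pandas as pd
    table = pd.DataFrame({"contig": ["c1"], "tss": [1000], "gene": ["gA"],
                          "strand": ["+"]})
    proms = extract_promoters(fasta, table, window=1000)
    assert proms["gA"].sequence == seq[0:1000]
    assert not proms["gA"].clipped


def test_minus_strand_window_is_reverse_complement(tmp_path, rng):
    import pandas as pd
    seq = "".join(rng.choice(list("ACGT"), size=1500))
    fasta = _write_fasta(tmp_path, {"c1": seq})
    table = pd.DataFrame({"contig": ["c1"], "tss": [200], "gene": ["gB"],
                          "strand": ["-"]})
    proms = extract_promoters(fasta, table, window=1000)
    assert proms["gB"].sequence == _manual_revcomp(seq[201:1201])


def test_clipped_window_is_flagged(tmp_path, rng):
    import pandas as pd
    seq = "".join(rng.choice(list("ACGT"), size=2000))
    fasta = _write_fasta(tmp_path, {"c1": seq})
    table = pd.DataFrame({"contig": ["c1"], "tss": [400], "gene": ["gC"],
                          "strand": ["+"]})
    proms = extract_promoters(fasta, table, window=1000)
    assert len(proms["gC"].sequence) == 400
    assert proms["gC"].clipped


def test_off_contig_tss_and_unknown_strand_rejected(tmp_path, rng):
    import pandas as pd
    fasta = _write_fasta(tmp_path, {"c1": "ACGT" * 100})
    bad_pos = pd.DataFrame({"contig": ["c1"], "tss": [5000], "gene": ["g"],
                            "strand": ["+"]})
    with pytest.raises(ValueError, match="off contig"):
        extract_promoters(fasta, bad_pos, window=100)
    bad_strand = pd.DataFrame({"contig": ["c1"], "tss": [50], "gene": ["g"],
                               "strand": ["."]})
    with pytest.raises(ValueError, match="strand"):
        extract_promoters(fasta, bad_strand, window=100)


def test_bed_and_gff_tss_agree(tmp_path):
    import pandas as pd
    bed = tmp_path / "t.bed"
    bed.write_text("c1\t500\t501\tgA\t0\t+\nc1\t120\t121\tgB\t0\t-\n")
    gff = tmp_path / "t.gff3"
    gff.write_text("##gff-version 3\n"
                   "c1\tsrc\tgene\t501\t900\t.\t+\t.\tID=gA\n"
                   "c1\tsrc\tgene\t20\t121\t.\t-\t.\tID=gB\n")
    t_bed = read_tss_table(bed).sort_values("gene").reset_index(drop=True)
    t_gff = read_tss_table(gff).sort_values("gene").reset_index(drop=True)
    assert (t_bed[["contig", "tss", "gene", "strand"]].values ==
            t_gff[["contig", "tss", "gene", "strand"]].values).all()


# -- PWM library I/O and TF→target map --------------------------------------------


def test_jaspar_round_trip(tmp_path):
    counts = generate_pwm_counts(3, seed=9)
    path = tmp_path / "pwms.txt"
    write_pwms(counts, path)
    lib = read_pwms(path)
    assert set(lib) == set(counts)
    for pid, c in counts.items():
        expected = c / c.sum(axis=0)
        assert np.allclose(lib[pid].matrix, expected, atol=1e-9)


def test_empty_tf_table_gives_empty_map():
    assert tf_target_map({}, {}, {}) == {}


def test_tf_without_pwm_is_skipped(rng):
    prom = Promoter("g", "".join(rng.choice(list("ACGT"), size=50)), "c", 0, 50, "+")
    assert tf_target_map({"tf1": "missing"}, {"g": prom}, {}, 0.9) == {}


def test_planted_pairs_recovered_from_study(study1):
    """Every planted TF→target pair is found when rescanning the promoters."""
    proms = {g: Promoter(g, s, "c", 0, len(s), "+")
             for g, s in study1.genome.promoters.items()}
    pairs = tf_target_map(study1.tf_table, proms, study1.pwms, rel_threshold=0.95)
    planted = study1.ledger.planted_pairs()
    assert planted <= set(pairs)
    # recorded offsets and strands score as perfect consensus hits
    for (tf, target), sites in study1.ledger.tf_targets.items():
        hits = {(h.offset, h.strand) for h in pairs[(tf, target)]
                if h.rel_score >= 1.0 - 1e-9}
        assert set(sites) <= hits
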