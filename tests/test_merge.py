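"""Read-pair overlap merging: worked examples, oracle equivalence, symmetry."""

from __future__ import annotations

import numpy as np
import pytest

from snodiff import MergeStats, SimConfig, merge_pair, merge_pairs, reverse_complement
from snodiff.merge import merge_library

from .conftest import brute_force_merge, naive_revcomp, sim_read_pairs


@pytest.mark.parametrize(
    "seq1, seq2, min_overlap, expected, overlap",
    [
        # full-length overlap of a 10-nt insert
        ("ACGTACGTAC", naive_revcomp("ACGTACGTAC"), 10, "ACGTACGTAC", 10),
        # short insert with adapter read-through on both sides: the 8-nt insert
        # is recovered and the overhangs AGAT / TCCA are discarded
        ("AACCGGTAAGAT", "TACCGGTTTGGA", 8, "AACCGGTA", 8),
    ],
)
def test_merge_pair_examples(seq1, seq2, min_overlap, expected, overlap):
    merged = merge_pair(seq1, seq2, min_overlap=min_overlap)
    assert merged is not None
    assert merged.sequence == expected
    assert merged.overlap_len == overlap


def test_no_complementarity_returns_nothing():
    assert merge_pair("AAAAAAAAAAAA", "CCCCCCCCCCCC", min_overlap=10) is None


def test_unequal_read_lengths_error():
    with pytest.raises(ValueError, match="unequal length"):
        merge_pair("ACGTACGTAC", "ACGTACGT")


def test_long_insert_spanning_both_reads():
    # 16-nt insert read by two 12-nt reads overlapping by 8
    insert = "ACGGTTACGATCCGTA"
    r1, r2 = insert[:12], naive_revcomp(insert[-12:])
    merged = merge_pair(r1, r2, min_overlap=8)
    assert merged is not None and merged.sequence == insert
    assert merged.overlap_len == 8


def test_ambiguous_best_placement_rejected():
    # two equally long exact overlaps (one at +4, one at -4, both 10 nt) tie;
    # the pair is rejected rather than risking a chimeric insert
    a = "ACGTTGCAACGTTG"
    b = "TGCA" + a[:10]
    assert b[4:] == a[:10] and a[4:] == b[:10]
    seq2 = naive_revcomp(b)
    assert brute_force_merge(a, seq2, min_overlap=10) is None
    assert merge_pair(a, seq2, min_overlap=10) is None


def test_n_bases_flagged_and_never_match():
    insert = "ACGTAACCGGTTAG"
    r1 = insert[:3] + "N" + insert[4:]
    merged = merge_pair(r1, naive_revcomp(insert), min_overlap=10)
    assert merged is not None
    assert merged.has_n and merged.sequence == insert[:3] + "N" + insert[4:]


def test_matches_bruteforce_on_simulated_pairs():
    """Fast seed-anchored merger equals the exhaustive-offset scorer on noisy
    simulated pairs (jitter, errors, adapters)."""
    cfg = SimConfig(
        n_loci=4, n_snp_loci=1, n_box_snp_loci=0, n_guide_snp_loci=0,
        n_silenced=0, depth_mean=60, depth_sigma=0.0, error_rate=0.01,
        seed=19,
    )
    from snodiff import build_strain_pair

    truth = build_strain_pair(cfg)
    n = 0
    for pair_id, s1, s2 in sim_read_pairs(truth, "B6", 0, cfg):
        got = merge_pair(s1, s2, min_overlap=10)
        expected = brute_force_merge(s1, s2, min_overlap=10)
        if expected is None:
            assert got is None, pair_id
        else:
            assert got is not None and (got.sequence, got.overlap_len) == expected
        n += 1
    assert n >= 200


def test_matches_bruteforce_with_mismatch_tolerance():
    rng = np.random.default_rng(23)
    bases = np.array(list("ACGT"))
    for _ in range(150):
        insert = "".join(rng.choice(bases, 30))
        r1 = (insert + "TGGAATTCTCGGGT")[:24]
        r2 = (naive_revcomp(insert) + "GATCGTCGGACTGT")[:24]
        # sprinkle a mismatch
        pos = int(rng.integers(0, 24))
        r1 = r1[:pos] + str(rng.choice(bases)) + r1[pos + 1 :]
        for frac in (0.0, 0.1):
            got = merge_pair(r1, r2, min_overlap=8, max_mismatch_frac=frac)
            expected = brute_force_merge(r1, r2, min_overlap=8, max_mismatch_frac=frac)
            if expected is None:
                assert got is None
            else:
                assert got is not None
                assert (got.sequence, got.overlap_len) == expected


def test_merge_is_symmetric_under_read_swap():
    rng = np.random.default_rng(5)
    bases = np.array(list("ACGT"))
    for _ in range(200):
        insert = "".join(rng.choice(bases, int(rng.integers(14, 40))))
        r1 = (insert + "TGGAATTCTCGGGTGCCAAGG")[:30]
        r2 = (naive_revcomp(insert) + "GATCGTCGGACTGTAGAACTC")[:30]
        fwd = merge_pair(r1, r2, min_overlap=10)
        rev = merge_pair(r2, r1, min_overlap=10)
        if fwd is None:
            assert rev is None
        else:
            assert rev is not None
            assert rev.sequence == reverse_complement(fwd.sequence)
            assert rev.overlap_len == fwd.overlap_len


def test_merge_pairs_stats_conservation(clean_truth, clean_config):
    stats = MergeStats()
    kept = list(
        merge_pairs(sim_read_pairs(clean_truth, "B6", 0, clean_config), stats=stats)
    )
    assert stats.pairs == stats.merged + stats.rejected
    assert stats.merged == stats.kept + stats.out_of_range
    assert len(kept) == stats.kept > 0


def test_noise_free_merge_recovers_every_manifest_insert(clean_truth, clean_config):
    from snodiff import simulate_library

    for rp, rec in simulate_library(clean_truth, "MSM", 0, clean_config):
        merged = merge_pair(rp.seq1, rp.seq2)
        assert merged is not None and merged.sequence == rec.insert


def test_merge_library_files_and_length_bounds(tmp_path, clean_truth, clean_config):
    from snodiff import write_library

    paths = write_library(clean_truth, "B6", 0, clean_config, tmp_path, gzip_fastq=True)
    stats = MergeStats()
    kept = list(merge_library(paths["r1"], paths["r2"], stats=stats))
    assert stats.pairs > 0 and stats.kept == len(kept)
    assert all(10 <= m.length <= 292 for m in kept)


def test_empty_fastq_yields_empty_stream(tmp_path):
    r1 = tmp_path / "empty_R1.fastq"
    r2 = tmp_path / "empty_R2.fastq"
    r1.write_text("")
    r2.write_text("")
    stats = MergeStats()
    assert list(merge_library(r1, r2, stats=stats)) == []
    assert stats == MergeStats()


def test_truncated_fastq_names_record(tmp_path):
    r1 = tmp_path / "a_R1.fastq"
    r2 = tmp_path / "a_R2.fastq"
    r1.write_text("@p1/1\nACGTACGTACGT\n+\nIIIIIIIIIIII\n@p2/1\nACGTACGTACGT\n+\nIIIIIIIIIIII\n")
    r2.write_text("@p1/2\nACGTACGTACGT\n+\nIIIIIIIIIIII\n")
    with pytest.raises(ValueError, match="p2"):
        list(merge_library(r1, r2))
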