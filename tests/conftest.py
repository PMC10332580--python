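"""Shared fixtures: small seeded simulations and an independent merge oracle."""

from __future__ import annotations

import pytest

from snodiff import SimConfig, build_strain_pair, simulate_library

_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N", "U": "A"}


def naive_revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq.upper()))


def brute_force_merge(
    seq1: str, seq2: str, min_overlap: int = 10, max_mismatch_frac: float = 0.0
):
    """Exhaustive-offset reference merger: scores every relative placement of
    read 1 against reverse-complemented read 2 by direct base comparison.
    Returns (insert, overlap_len) or None. Kept deliberately naive."""
    s1 = seq1.upper()
    r2rc = naive_revcomp(seq2)
    L = len(s1)
    candidates = []
    for d in range(-(L - min_overlap), L - min_overlap + 1):
        a, b = max(d, 0), min(d + L, L)
        window = b - a
        if window < min_overlap:
            continue
        matches = mismatches = 0
        for x, y in zip(s1[a - d : b - d], r2rc[a:b]):
            if x == "N" or y == "N":
                continue
            if x == y:
                matches += 1
            else:
                mismatches += 1
        if mismatches <= max_mismatch_frac * window:
            candidates.append((matches, d))
    if not candidates:
        return None
    best = max(m for m, _ in candidates)
    offsets = [d for m, d in candidates if m == best]
    if len(offsets) != 1:
        return None
    d = offsets[0]
    insert = s1[: L - d] if d >= 0 else s1 + r2rc[L + d :]
    return insert, L - abs(d)


def sim_read_pairs(truth, strain, library_index, config):
    """(pair_id, seq1, seq2) triples straight from the simulator."""
    for rp, _ in simulate_library(truth, strain, library_index, config):
        yield rp.id, rp.seq1, rp.seq2


@pytest.fixture(scope="session")
def tiny_config() -> SimConfig:
    """Small but fully featured study: SNP loci in box/guide/spacer regions,
    one locus silenced in B6, modest depth."""
    return SimConfig(
        n_loci=8,
        n_snp_loci=3,
        n_box_snp_loci=1,
        n_guide_snp_loci=1,
        n_silenced=1,
        depth_mean=300,
        depth_sigma=0.0,
        seed=7,
    )


@pytest.fixture(scope="session")
def tiny_truth(tiny_config):
    return build_strain_pair(tiny_config)


@pytest.fixture(scope="session")
def clean_config() -> SimConfig:
    """Noise-free limit: no errors, no contamination, no end jitter."""
    return SimConfig(
        n_loci=4,
        n_snp_loci=2,
        n_box_snp_loci=0,
        n_guide_snp_loci=0,
        n_silenced=0,
        depth_mean=40,
        depth_sigma=0.0,
        error_rate=0.0,
        contamination_rate=0.0,
        end_jitter=0,
        seed=3,
    )


@pytest.fixture(scope="session")
def clean_truth(clean_config):
    return build_strain_pair(clean_config)
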