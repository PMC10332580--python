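"""Published summary counts from the B6 x MSM brain small-RNA comparison that
this pipeline re-implements, shipped as worked-example inputs.

``library_summary`` holds, for each of the three library preparations
("analyses") and each strain, the number of merged RNA sequences (the rpm
denominator, called the read number) and the number of distinct sequence types.
``snord_read_counts`` holds the per-sequence-type read numbers of the detected
box C/D snoRNAs in each strain's libraries, with the SNP count of each paired
MSM type against its B6 counterpart. These printed values are used for
arithmetic bookkeeping checks and for the worked selection-rule example; they
are data, not results computed by this package.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["library_summary", "snord_read_counts", "TOTAL_MERGED_SEQUENCES"]

# sum of the six per-library merged-sequence counts
TOTAL_MERGED_SEQUENCES = 27_261_887

_LIBRARY_SUMMARY = [
    # (analysis, strain, merged_reads, distinct_sequences)
    (1, "B6", 5_210_785, 180_679),
    (1, "MSM", 5_498_823, 190_655),
    (2, "B6", 3_767_220, 319_431),
    (2, "MSM", 4_014_677, 359_410),
    (3, "B6", 4_141_045, 381_742),
    (3, "MSM", 4_629_337, 406_614),
]

_SNORD_READ_COUNTS = [
    # (rna, type_label, reads_b6, reads_msm, snp_count or None)
    ("SNORD31 (Gm23246)", "B6", 21_355, 20, None),
    ("SNORD31 (Gm23246)", "MSM", 8, 7_752, 1),
    ("SNORD33", "B6", 9_463, 10, None),
    ("SNORD33", "MSM", 0, 12_135, 1),
    ("SNORD38 (Gm22980)", "B6", 17_261, 0, None),
    ("SNORD38 (Gm22980)", "MSM", 2, 10_692, 1),
    ("SNORD45c (Gm24494)", "B6", 25_907, 19, None),
    ("SNORD45c (Gm24494)", "MSM", 39, 33_028, 1),
    ("SNORD49b", "B6-1", 6_951, 63, None),
    ("SNORD49b", "MSM-1", 33, 5_347, 2),
    ("SNORD49b", "MSM-2", 4, 1_239, 2),
    ("SNORD52", "B6", 13_247, 19, None),
    ("SNORD52", "MSM", 11, 11_995, 1),
    ("SNORD53", "MSM", 0, 8_990, 1),
    ("SNORD58b (Gm23301)", "B6-1", 9_445, 5, None),
    ("SNORD58b (Gm23301)", "B6-2", 22_196, 8, None),
    ("SNORD58b (Gm23301)", "MSM", 16, 21_664, 1),
    ("SNORD58b (Gm26202)", "B6", 33_586, 22, None),
    ("SNORD58b (Gm26202)", "MSM", 3, 62_312, 1),
    ("SNORD100", "B6", 4_345, 0, None),
    ("SNORD100", "MSM", 0, 5_793, 1),
    ("SNORD115", "B6-1", 43_489, 20, None),
    ("SNORD115", "B6-2", 2_750, 19, None),
    ("SNORD115", "B6-3", 3_805, 6, None),
    ("SNORD115", "B6-4", 21_571, 0, None),
    ("SNORD115", "B6-5", 3_393, 0, None),
    ("SNORD115", "MSM-1", 0, 35_958, 4),
    ("SNORD115", "MSM-2", 3, 4_438, 1),
    ("SNORD116", "B6-1", 6_211, 14, None),
    ("SNORD116", "B6-2", 4_486, 26, None),
    ("SNORD116", "B6-3", 2_856, 5, None),
    ("SNORD116", "MSM", 0, 3_330, 1),
]


def library_summary() -> pd.DataFrame:
    """Per-library merged-sequence and distinct-sequence counts."""
    return pd.DataFrame(
        _LIBRARY_SUMMARY,
        columns=["analysis", "strain", "merged_reads", "distinct_sequences"],
    )


def snord_read_counts() -> pd.DataFrame:
    """Per-sequence-type read numbers of the detected SNORDs (both strains'
    totals for each type, plus the SNP count of paired MSM types)."""
    df = pd.DataFrame(
        _SNORD_READ_COUNTS,
        columns=["rna", "type", "reads_b6", "reads_msm", "snp_count"],
    )
    df["snp_count"] = df["snp_count"].astype("Int64")
    return df
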