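"""Strain comparison, the selection rule, category bins, fragment collapsing
and cross-analysis intersection."""

from __future__ import annotations

import math

import pytest

from snodiff import (
    ComparisonRecord,
    SelectionThresholds,
    categorize,
    collapse_fragments,
    compare_strains,
    intersect_common,
    select_differential,
)
from snodiff.tables import snord_read_counts


@pytest.mark.parametrize(
    "rpm, category",
    [(0.0, 1), (9.999, 1), (10.0, 2), (99.9, 2), (100.0, 3), (999.0, 3),
     (1000.0, 4), (54321.0, 4)],
)
def test_categorize_bins(rpm, category):
    assert categorize(rpm) == category


def test_categorize_rejects_negative():
    with pytest.raises(ValueError):
        categorize(-1.0)


def test_compare_strains_status_and_fold():
    records = compare_strains({"S1": 21_355.0, "S2": 50.0}, {"S1": 20.0, "S3": 8_990.0})
    by_seq = {r.sequence: r for r in records}
    assert by_seq["S1"].status == "both"
    assert by_seq["S1"].fold == pytest.approx(21_355 / 20)
    assert by_seq["S2"].status == "b6_only" and by_seq["S2"].category == 2
    assert by_seq["S3"].status == "msm_only" and by_seq["S3"].fold == math.inf
    assert by_seq["S3"].category == 4


def test_equal_values_fold_one():
    (rec,) = compare_strains({"S": 42.0}, {"S": 42.0})
    assert rec.fold == pytest.approx(1.0)


@pytest.mark.parametrize(
    "b6, msm, selected, bias",
    [
        (39.0, 33_028.0, True, "MSM"),   # ~847-fold
        (50.0, 60.0, False, None),       # sub-threshold
        (50.0, 0.0, False, None),        # one-strain-only below 100 rpm (category 2)
        (100.0, 0.0, True, "B6"),        # one-strain-only at the threshold
        (101.0, 1.0, True, "B6"),        # just over 100-fold
        (100.0, 1.0, False, None),       # exactly 100-fold is not "more than"
    ],
)
def test_selection_rule(b6, msm, selected, bias):
    records = compare_strains({"S": b6} if b6 else {}, {"S": msm} if msm else {})
    result = select_differential(records)
    assert result.records[0].selected is selected
    assert result.records[0].bias == bias


def test_printed_snord_counts_classify_to_printed_labels():
    """Every published per-type count pair classifies to its printed strain."""
    df = snord_read_counts()
    rpm_b6 = {f"T{i}": float(v) for i, v in enumerate(df.reads_b6) if v > 0}
    rpm_msm = {f"T{i}": float(v) for i, v in enumerate(df.reads_msm) if v > 0}
    result = select_differential(compare_strains(rpm_b6, rpm_msm))
    by_seq = {r.sequence: r for r in result.records}
    for i, type_label in enumerate(df["type"]):
        rec = by_seq[f"T{i}"]
        assert rec.selected, (df.rna[i], type_label)
        assert rec.bias == ("B6" if type_label.startswith("B6") else "MSM")


def test_selection_symmetric_under_strain_swap():
    rpm_a = {"S1": 5000.0, "S2": 10.0, "S3": 120.0, "S4": 7.0}
    rpm_b = {"S1": 4.0, "S2": 11.0, "S4": 7.0, "S5": 900.0}
    fwd = select_differential(compare_strains(rpm_a, rpm_b))
    swapped = select_differential(compare_strains(rpm_b, rpm_a))
    sel_fwd = {r.sequence: r.bias for r in fwd.selected}
    sel_swp = {r.sequence: r.bias for r in swapped.selected}
    assert set(sel_fwd) == set(sel_swp)
    flip = {"B6": "MSM", "MSM": "B6"}
    assert {s: flip[b] for s, b in sel_fwd.items()} == sel_swp


def test_selection_monotone_in_fold_threshold():
    rpm_a = {f"S{i}": float(10 * i + 1) for i in range(1, 30)}
    rpm_b = {f"S{i}": float(1 + i % 7) for i in range(1, 30)}
    records = compare_strains(rpm_a, rpm_b)
    previous = None
    for fold in (2, 5, 10, 50, 100, 500):
        chosen = {
            r.sequence
            for r in select_differential(
                records, SelectionThresholds(fold_threshold=fold)
            ).selected
        }
        if previous is not None:
            assert chosen <= previous
        previous = chosen


def _rec(seq: str, b6: float, msm: float) -> ComparisonRecord:
    return ComparisonRecord(seq, b6, msm, "both", 1.0)


def test_collapse_by_containment_without_references():
    records = [
        _rec("ACGTACGTACGT", 10.0, 0.0),
        _rec("CGTACGTACG", 5.0, 0.0),   # substring of the first
        _rec("TTTTGGGGCCCC", 0.0, 7.0),  # unrelated
    ]
    groups, ungrouped = collapse_fragments(records)
    assert len(groups) == 2 and not ungrouped
    big = next(g for g in groups if len(g.members) == 2)
    assert big.total_rpm_b6 == pytest.approx(15.0)
    assert big.strain_bias == "B6"


def test_collapse_against_references_exact_and_near_match():
    ref_b6 = {"SNO1": "AAGGACGTACGTACGTTCC", "SNO2": "TTGGCATCATCATGGAA"}
    ref_msm = {"SNO1": "AAGGACGTACGAACGTTCC", "SNO2": "TTGGCATCATCATGGAA"}
    records = [
        _rec("ACGTACGTACGT", 9.0, 0.0),   # exact in B6 SNO1
        _rec("ACGTACGAACGT", 0.0, 8.0),   # exact in MSM SNO1 (allele)
        _rec("GCATCATCATGG", 4.0, 4.0),   # exact in SNO2
        _rec("ACGTACCAACGT", 0.0, 2.0),   # 1 substitution from MSM SNO1
    ]
    groups, ungrouped = collapse_fragments(records, ref_b6, ref_msm)
    assert not ungrouped
    by_ref = {g.reference_id: g for g in groups}
    assert set(by_ref) == {"SNO1", "SNO2"}
    assert len(by_ref["SNO1"].members) == 3
    total = sum(g.total_rpm_b6 + g.total_rpm_msm for g in groups)
    assert total == pytest.approx(sum(r.rpm_b6 + r.rpm_msm for r in records))


def test_collapse_flags_ambiguous_matches():
    refs = {"A": "AAGGACGTACGTACGTTCC", "B": "TTACGTACGTACGTGG"}
    records = [_rec("ACGTACGTACGT", 3.0, 0.0)]
    groups, ungrouped = collapse_fragments(records, refs)
    assert groups == []
    assert len(ungrouped) == 1 and ungrouped[0][3] == "ambiguous"


def test_collapse_conserves_rpm_mass_on_simulation(tiny_truth, tiny_config):
    from snodiff import merge_pairs, tally, to_rpm

    from .conftest import sim_read_pairs

    refs_b6 = {i: l.sequence for i, l in tiny_truth.loci_b6.items()}
    refs_msm = {i: l.sequence for i, l in tiny_truth.loci_msm.items()}
    rpm = {}
    for strain in ("B6", "MSM"):
        table = tally(
            merge_pairs(sim_read_pairs(tiny_truth, strain, 0, tiny_config)),
            strain=strain,
        )
        rpm[strain] = to_rpm(table)
    result = select_differential(compare_strains(rpm["B6"], rpm["MSM"]))
    groups, ungrouped = collapse_fragments(result.selected, refs_b6, refs_msm)
    grouped_mass = sum(g.total_rpm_b6 + g.total_rpm_msm for g in groups)
    member_mass = sum(
        r.rpm_b6 + r.rpm_msm for r in result.selected
    ) - sum(b6 + msm for _, b6, msm, _ in ungrouped)
    assert grouped_mass == pytest.approx(member_mass)


@pytest.mark.parametrize(
    "sets, expected",
    [
        ([{"A", "B", "C"}, {"B", "C"}, {"B", "C", "D"}], {"B", "C"}),
        ([{"X", "Y"}], {"X", "Y"}),
        ([{"A"}, {"B"}], set()),
    ],
)
def test_intersect_common(sets, expected):
    assert intersect_common(sets) == expected


def test_intersect_requires_a_set():
    with pytest.raises(ValueError):
        intersect_common([])
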