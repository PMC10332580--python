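"""Differential selection between strains, category binning, fragment
collapsing and cross-analysis intersection.

Per analysis (one library preparation per strain), every sequence type's rpm in
the two strains is compared. A type is *selected* as differential when both
strains express it and the larger rpm exceeds the smaller by more than the fold
threshold (default 100), or when one strain's rpm is zero and the other's is at
least the only-threshold (default 100 rpm). Types seen in a single strain are
additionally binned into categories 1-4 by rpm (x < 10, 10 <= x < 100,
100 <= x < 1000, 1000 <= x).

Because snoRNA processing and degradation produce fragments with ragged 5'/3'
ends, selected sequence types are collapsed to snoRNA-level groups by matching
them against reference snoRNA sequences (exact substring first, then best
ungapped near-match), and the groups' reference ids are intersected across the
analyses to find the robustly differential snoRNAs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .counts import RpmTable, canonical

__all__ = [
    "SelectionThresholds",
    "ComparisonRecord",
    "SelectionResult",
    "FragmentGroup",
    "categorize",
    "compare_strains",
    "select_differential",
    "collapse_fragments",
    "intersect_common",
]


def categorize(rpm_value: float) -> int:
    """rpm bin for one-strain-only sequences: 1: x < 10; 2: 10 <= x < 100;
    3: 100 <= x < 1000; 4: 1000 <= x. Boundaries fall in the upper bin."""
    if rpm_value < 0:
        raise ValueError(f"rpm must be non-negative, got {rpm_value}")
    if rpm_value < 10:
        return 1
    if rpm_value < 100:
        return 2
    if rpm_value < 1000:
        return 3
    return 4


@dataclass(frozen=True)
class SelectionThresholds:
    """fold_threshold: minimum fold excess (strict) when both strains express a
    type; only_threshold: minimum rpm (inclusive) when the other strain is 0."""

    fold_threshold: float = 100.0
    only_threshold: float = 100.0

    def __post_init__(self) -> None:
        if self.fold_threshold <= 0 or self.only_threshold <= 0:
            raise ValueError("selection thresholds must be positive")


@dataclass
class ComparisonRecord:
    """One sequence type's strain comparison. ``fold`` is max/min of the two
    rpm values when both are positive, infinite otherwise; ``category`` is set
    only for one-strain-only types."""

    sequence: str
    rpm_b6: float
    rpm_msm: float
    status: str  # both | b6_only | msm_only
    fold: float
    category: int | None = None
    selected: bool = False
    bias: str | None = None  # B6 | MSM when selected


def compare_strains(
    rpm_b6: RpmTable | Mapping[str, float],
    rpm_msm: RpmTable | Mapping[str, float],
) -> list[ComparisonRecord]:
    """Union of the two strains' sequence types with per-type comparison;
    a type absent from one table has rpm 0 there."""
    m_b6 = rpm_b6.rpm if isinstance(rpm_b6, RpmTable) else dict(rpm_b6)
    m_msm = rpm_msm.rpm if isinstance(rpm_msm, RpmTable) else dict(rpm_msm)
    records = []
    for seq in sorted(set(m_b6) | set(m_msm)):
        b6 = float(m_b6.get(seq, 0.0))
        msm = float(m_msm.get(seq, 0.0))
        if b6 > 0 and msm > 0:
            status = "both"
            fold = max(b6, msm) / min(b6, msm)
            category = None
        else:
            status = "b6_only" if b6 > 0 else "msm_only"
            fold = math.inf
            category = categorize(max(b6, msm))
        records.append(
            ComparisonRecord(
                sequence=canonical(seq),
                rpm_b6=b6,
                rpm_msm=msm,
                status=status,
                fold=fold,
                category=category,
            )
        )
    return records


@dataclass
class SelectionResult:
    records: list[ComparisonRecord]
    thresholds: SelectionThresholds

    @property
    def selected(self) -> list[ComparisonRecord]:
        return [r for r in self.records if r.selected]

    @property
    def selected_b6(self) -> list[ComparisonRecord]:
        return [r for r in self.records if r.selected and r.bias == "B6"]

    @property
    def selected_msm(self) -> list[ComparisonRecord]:
        return [r for r in self.records if r.selected and r.bias == "MSM"]


def select_differential(
    records: Iterable[ComparisonRecord],
    thresholds: SelectionThresholds | None = None,
) -> SelectionResult:
    """Apply the strain-specificity rule: selected iff both rpm are positive
    with fold > fold_threshold, or one rpm is zero and the other is at least
    only_threshold. Selected records are labeled by the larger side."""
    if thresholds is None:
        thresholds = SelectionThresholds()
    out = []
    for rec in records:
        if rec.status == "both":
            hit = rec.fold > thresholds.fold_threshold
        else:
            hit = max(rec.rpm_b6, rec.rpm_msm) >= thresholds.only_threshold
        bias = ("B6" if rec.rpm_b6 > rec.rpm_msm else "MSM") if hit else None
        out.append(replace(rec, selected=hit, bias=bias))
    return SelectionResult(records=out, thresholds=thresholds)


@dataclass
class FragmentGroup:
    """End-variant fragments collapsed to one snoRNA. ``members`` holds
    (sequence, rpm_b6, rpm_msm) tuples; totals are the rpm sums."""

    group_id: str
    reference_id: str | None
    members: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def total_rpm_b6(self) -> float:
        return sum(m[1] for m in self.members)

    @property
    def total_rpm_msm(self) -> float:
        return sum(m[2] for m in self.members)

    @property
    def strain_bias(self) -> str:
        b6, msm = self.total_rpm_b6, self.total_rpm_msm
        if b6 == msm:
            return "equal"
        return "B6" if b6 > msm else "MSM"


def _best_substring_subs(frag: str, ref: str, budget: int) -> int:
    """Fewest substitutions over all full placements of frag inside ref
    (budget+1 when none fits within budget or frag is longer than ref)."""
    if len(frag) > len(ref):
        return budget + 1
    best = budget + 1
    for start in range(len(ref) - len(frag) + 1):
        subs = 0
        window = ref[start : start + len(frag)]
        for x, y in zip(frag, window):
            if x != y:
                subs += 1
                if subs >= best:
                    break
        best = min(best, subs)
        if best == 0:
            return 0
    return best


def _assign_reference(
    seq: str,
    refsets: Sequence[Mapping[str, str]],
    max_substitutions: int,
) -> tuple[str | None, bool]:
    """(reference_id, ambiguous). Exact substring containment wins; otherwise
    the single reference with fewest substitutions at the best ungapped
    placement (<= max_substitutions)."""
    exact = set()
    for refs in refsets:
        for rid, rseq in refs.items():
            if seq in rseq:
                exact.add(rid)
    if len(exact) == 1:
        return exact.pop(), False
    if len(exact) > 1:
        return None, True
    best_ids: set[str] = set()
    best = max_substitutions + 1
    for refs in refsets:
        for rid, rseq in refs.items():
            subs = _best_substring_subs(seq, rseq, max_substitutions)
            if subs < best:
                best, best_ids = subs, {rid}
            elif subs == best:
                best_ids.add(rid)
    if best > max_substitutions:
        return None, False
    if len(best_ids) > 1:
        return None, True
    return best_ids.pop(), False


def _containment_groups(seqs: list[str]) -> list[list[str]]:
    """Group sequences related by substring containment (transitively)."""
    parent = list(range(len(seqs)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(seqs)):
        for j in range(i + 1, len(seqs)):
            if seqs[i] in seqs[j] or seqs[j] in seqs[i]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[rj] = ri
    buckets: dict[int, list[str]] = {}
    for i, s in enumerate(seqs):
        buckets.setdefault(find(i), []).append(s)
    return [buckets[k] for k in sorted(buckets)]


def collapse_fragments(
    records: Iterable,
    references: Mapping[str, str] | None = None,
    references_alt: Mapping[str, str] | None = None,
    *,
    max_substitutions: int = 4,
) -> tuple[list[FragmentGroup], list]:
    """Collapse end-variant fragments to snoRNA-level groups.

    ``records`` need ``sequence``, ``rpm_b6`` and ``rpm_msm`` attributes (a
    selection's records qualify). With reference sets (e.g. the two strains'
    snoRNA sequences under shared ids) each fragment joins the reference that
    contains it; without references, fragments are grouped by substring
    containment. Returns (groups, ungrouped) where ungrouped holds fragments
    that matched no reference or several equally well (flagged ambiguous).
    """
    items = [
        (canonical(r.sequence), float(r.rpm_b6), float(r.rpm_msm)) for r in records
    ]
    groups: dict[str, FragmentGroup] = {}
    ungrouped: list[tuple[str, float, float, str]] = []

    if references is not None:
        refsets = [{k: canonical(v) for k, v in references.items()}]
        if references_alt is not None:
            refsets.append({k: canonical(v) for k, v in references_alt.items()})
        for seq, b6, msm in items:
            rid, ambiguous = _assign_reference(seq, refsets, max_substitutions)
            if rid is None:
                ungrouped.append((seq, b6, msm, "ambiguous" if ambiguous else "unassigned"))
                continue
            groups.setdefault(rid, FragmentGroup(group_id=rid, reference_id=rid))
            groups[rid].members.append((seq, b6, msm))
        return [groups[k] for k in sorted(groups)], ungrouped

    by_seq: dict[str, tuple[float, float]] = {}
    for seq, b6, msm in items:
        prev = by_seq.get(seq, (0.0, 0.0))
        by_seq[seq] = (prev[0] + b6, prev[1] + msm)
    clusters = _containment_groups(sorted(by_seq))
    out = []
    for idx, cluster in enumerate(clusters, start=1):
        g = FragmentGroup(group_id=f"group{idx}", reference_id=None)
        for seq in cluster:
            b6, msm = by_seq[seq]
            g.members.append((seq, b6, msm))
        out.append(g)
    return out, ungrouped


def intersect_common(id_sets: Iterable[Iterable[str]]) -> set[str]:
    """Reference ids selected in every analysis (exact set intersection)."""
    sets = [set(s) for s in id_sets]
    if not sets:
        raise ValueError("need at least one id set to intersect")
    common = sets[0]
    for s in sets[1:]:
        common &= s
    return common


def selection_frame(result: SelectionResult) -> pd.DataFrame:
    """TSV-ready per-sequence comparison/selection table (also usable as
    scatter-plot data: rpm_b6 vs rpm_msm)."""
    return pd.DataFrame(
        {
            "sequence": [r.sequence for r in result.records],
            "rpm_b6": [r.rpm_b6 for r in result.records],
            "rpm_msm": [r.rpm_msm for r in result.records],
            "status": [r.status for r in result.records],
            "fold": [r.fold for r in result.records],
            "category": [r.category if r.category is not None else "" for r in result.records],
            "selected": [r.selected for r in result.records],
            "bias": [r.bias or "" for r in result.records],
        }
    )
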