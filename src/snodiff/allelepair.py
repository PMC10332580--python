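"""Pairing of strain-specific sequence types as alleles and SNP counting.

A differentially detected snoRNA usually appears as one sequence type specific
to C57BL/6 (B6) and one specific to MSM/Ms (MSM) that differ only by a few
substitutions -- the SNPs that make the alleles distinguishable. Alignment is
ungapped: sequence types are slid against each other over a window of offsets
and the offset with the most matching bases wins, so the SNP count is simply
the Hamming distance of the overlapping window. Types without a counterpart
within the substitution budget are strain-exclusive (the SNORD53 pattern: the
snoRNA is seen in one strain only).
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .counts import canonical

__all__ = [
    "SequenceType",
    "AllelePair",
    "best_ungapped_offset",
    "pair_alleles",
    "snps_vs_reference",
]


def best_ungapped_offset(
    seq_a: str,
    seq_b: str,
    max_shift: int | None = None,
    min_overlap: int = 10,
) -> tuple[int, int, int] | None:
    """Best ungapped placement of ``seq_b`` against ``seq_a``.

    Offset ``k`` aligns ``seq_b[i]`` with ``seq_a[i + k]`` (so a sequence
    5'-trimmed by 3 nt aligns to its source at offset 3). Returns
    ``(offset, matches, substitutions)`` for the offset maximizing matching
    bases in the overlapping window; ties prefer the smallest ``|offset|``,
    then the negative one. Positions where either base is N count neither as
    match nor as substitution. Returns None when no offset leaves an overlap
    of at least ``min_overlap``.
    """
    a = canonical(seq_a)
    b = canonical(seq_b)
    if not a or not b:
        raise ValueError("cannot align an empty sequence")
    la, lb = len(a), len(b)
    lo, hi = -(lb - min_overlap), la - min_overlap
    if max_shift is not None:
        lo, hi = max(lo, -max_shift), min(hi, max_shift)
    best: tuple[int, int, int] | None = None  # (matches, -rank, ...) handled below
    for k in range(lo, hi + 1):
        a_start, a_end = max(k, 0), min(la, k + lb)
        window = a_end - a_start
        if window < min_overlap:
            continue
        matches = subs = 0
        for x, y in zip(a[a_start:a_end], b[a_start - k : a_end - k]):
            if x == "N" or y == "N":
                continue
            if x == y:
                matches += 1
            else:
                subs += 1
        # tie order: more matches, then smaller |offset|, then negative first
        key = (matches, -abs(k), -(k >= 0))
        if best is None or key > best[0]:
            best = (key, k, matches, subs)
    if best is None:
        return None
    _, k, matches, subs = best
    return k, matches, subs


def _window_mismatch_positions(a: str, b: str, k: int) -> list[int]:
    """Positions (in ``a`` coordinates) where the overlap at offset k differs."""
    a_start, a_end = max(k, 0), min(len(a), k + len(b))
    out = []
    for i in range(a_start, a_end):
        x, y = a[i], b[i - k]
        if x != "N" and y != "N" and x != y:
            out.append(i)
    return out


@dataclass
class SequenceType:
    """A distinct sequence with its read support in each strain's libraries."""

    sequence: str
    count_b6: float = 0.0
    count_msm: float = 0.0


@dataclass
class AllelePair:
    """A B6-specific and an MSM-specific sequence type matched as alleles.

    ``snp_positions`` are 0-based on the B6 type's coordinate frame;
    ``exclusivity`` is 'paired' when both types exist, otherwise
    'b6_exclusive'/'msm_exclusive'. ``ambiguous`` marks types that matched
    more than one counterpart equally well (near-identical cluster copies).
    """

    reference_id: str | None
    b6_type: SequenceType | None
    msm_type: SequenceType | None
    offset: int | None
    snp_positions: list[int]
    exclusivity: str
    ambiguous: bool = False

    @property
    def snp_count(self) -> int:
        return len(self.snp_positions)


def _representative(group) -> SequenceType:
    """Highest-support member of a fragment group as (sequence, counts)."""
    best = max(group.members, key=lambda m: (m[1] + m[2], m[0]))
    return SequenceType(sequence=best[0], count_b6=best[1], count_msm=best[2])


def pair_alleles(
    b6_groups,
    msm_groups,
    max_snp: int = 4,
    min_overlap: int = 10,
    max_shift: int | None = None,
) -> list[AllelePair]:
    """Match strain-biased fragment groups into allele pairs.

    Each group is represented by its highest-support sequence. Pairs are
    mutual best matches (fewest substitutions at the best ungapped offset)
    with at most ``max_snp`` substitutions; a group tying against several
    counterparts yields one pair per counterpart, flagged ambiguous (the
    SNORD115/116 cluster situation). Unmatched groups become exclusives.
    """
    b6_groups = list(b6_groups)
    msm_groups = list(msm_groups)
    reps_b6 = [_representative(g) for g in b6_groups]
    reps_msm = [_representative(g) for g in msm_groups]

    table: dict[tuple[int, int], tuple[int, int]] = {}  # (i,j) -> (subs, offset)
    for i, rb in enumerate(reps_b6):
        for j, rm in enumerate(reps_msm):
            hit = best_ungapped_offset(
                rb.sequence, rm.sequence, max_shift=max_shift, min_overlap=min_overlap
            )
            if hit is None:
                continue
            offset, _, subs = hit
            if subs <= max_snp:
                table[(i, j)] = (subs, offset)

    row_min = {i: min(s for (x, _), (s, _) in table.items() if x == i)
               for i in {x for x, _ in table}}
    col_min = {j: min(s for (_, y), (s, _) in table.items() if y == j)
               for j in {y for _, y in table}}

    pairs: list[AllelePair] = []
    matched_b6: set[int] = set()
    matched_msm: set[int] = set()
    mutual = [
        (i, j)
        for (i, j), (subs, _) in sorted(table.items())
        if subs == row_min[i] and subs == col_min[j]
    ]
    row_hits = {i: sum(1 for x, _ in mutual if x == i) for i, _ in mutual}
    col_hits = {j: sum(1 for _, y in mutual if y == j) for _, j in mutual}
    for i, j in mutual:
        subs, offset = table[(i, j)]
        rb, rm = reps_b6[i], reps_msm[j]
        ref = getattr(b6_groups[i], "reference_id", None) or getattr(
            msm_groups[j], "reference_id", None
        )
        pairs.append(
            AllelePair(
                reference_id=ref,
                b6_type=rb,
                msm_type=rm,
                offset=offset,
                snp_positions=_window_mismatch_positions(
                    canonical(rb.sequence), canonical(rm.sequence), offset
                ),
                exclusivity="paired",
                ambiguous=row_hits[i] > 1 or col_hits[j] > 1,
            )
        )
        matched_b6.add(i)
        matched_msm.add(j)

    for i, rb in enumerate(reps_b6):
        if i not in matched_b6:
            pairs.append(
                AllelePair(
                    reference_id=getattr(b6_groups[i], "reference_id", None),
                    b6_type=rb,
                    msm_type=None,
                    offset=None,
                    snp_positions=[],
                    exclusivity="b6_exclusive",
                )
            )
    for j, rm in enumerate(reps_msm):
        if j not in matched_msm:
            pairs.append(
                AllelePair(
                    reference_id=getattr(msm_groups[j], "reference_id", None),
                    b6_type=None,
                    msm_type=rm,
                    offset=None,
                    snp_positions=[],
                    exclusivity="msm_exclusive",
                )
            )
    pairs.sort(key=lambda p: (p.reference_id or "", p.exclusivity))
    return pairs


def snps_vs_reference(
    allele_sequence: str,
    reference_sequence: str,
    max_snp: int = 4,
    min_overlap: int = 10,
    max_shift: int | None = None,
) -> list[int] | None:
    """Substitution positions of an allele against a reference snoRNA, in
    0-based reference coordinates; None when the substitution load exceeds
    ``max_snp`` (unalignable under the ungapped model)."""
    ref = canonical(reference_sequence)
    allele = canonical(allele_sequence)
    hit = best_ungapped_offset(ref, allele, max_shift=max_shift, min_overlap=min_overlap)
    if hit is None:
        return None
    offset, _, subs = hit
    if subs > max_snp:
        return None
    return _window_mismatch_positions(ref, allele, offset)


def allele_table(pairs: list[AllelePair]) -> pd.DataFrame:
    """Per-type read-number table (reference, type label, counts, SNPs)."""
    rows = []
    for p in pairs:
        for label, t in (("B6", p.b6_type), ("MSM", p.msm_type)):
            if t is None:
                continue
            rows.append(
                {
                    "reference_id": p.reference_id or "",
                    "type": label,
                    "sequence": t.sequence,
                    "count_b6": t.count_b6,
                    "count_msm": t.count_msm,
                    "snp_count": p.snp_count if p.exclusivity == "paired" else "",
                    "exclusivity": p.exclusivity,
                    "ambiguous": p.ambiguous,
                }
            )
    return pd.DataFrame(rows)
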