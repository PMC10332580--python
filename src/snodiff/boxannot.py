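"""Box C/D element annotation and SNP classification on snoRNA sequences.

A box C/D snoRNA carries a C box (consensus RUGAUGA) near its 5' end and a D
box (consensus CUGA) near its 3' end, often with an internal, degenerate copy
of the D box (the D' box). Immediately 5' of the D or D' box may sit the
antisense guide element, a stretch complementary to the target RNA that directs
2'-O-methylation. SNPs between strains are classified by which of these
intervals they fall in; a SNP outside all of them is functionally silent, while
a SNP in a box can abolish expression of the allele (the SNORD53 pattern, where
one strain's allele has a mutated CUGA box and is not detected).

Sequences are handled as DNA internally (U -> T); coordinates are 0-based,
half-open.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from .counts import canonical

__all__ = [
    "BoxMatch",
    "BoxAnnotation",
    "SnpClassification",
    "find_boxes",
    "find_guide",
    "classify_snp",
]

_IUPAC = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

# Watson-Crick pairs plus the G.U wobble, as (guide base, target base)
_WC_PAIRS = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G")}
_GU_PAIRS = _WC_PAIRS | {("G", "T"), ("T", "G")}


def _mismatches(seq: str, start: int, consensus: str) -> int:
    n = 0
    for i, c in enumerate(consensus):
        if seq[start + i] not in _IUPAC[c]:
            n += 1
    return n


def _candidates(seq: str, consensus: str, max_mismatch: int, lo: int, hi: int):
    """(start, mismatches) for every placement of consensus within [lo, hi)."""
    for start in range(max(lo, 0), min(hi, len(seq)) - len(consensus) + 1):
        mm = _mismatches(seq, start, consensus)
        if mm <= max_mismatch:
            yield start, mm


@dataclass
class BoxMatch:
    start: int
    end: int
    text: str
    mismatches: int

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.end)


@dataclass
class BoxAnnotation:
    """Box and guide intervals on one snoRNA sequence. ``non_canonical`` is set
    when the C or D box is missing within its mismatch budget."""

    sequence: str
    c_box: BoxMatch | None = None
    d_box: BoxMatch | None = None
    d_prime_box: BoxMatch | None = None
    guide_intervals: list[tuple[int, int]] = field(default_factory=list)
    non_canonical: bool = False

    @property
    def length(self) -> int:
        return len(self.sequence)


def find_boxes(
    sequence: str,
    c_box_consensus: str = "RTGATGA",
    d_box_consensus: str = "CTGA",
    *,
    c_max_mismatch: int = 1,
    d_max_mismatch: int = 0,
    d_prime_max_mismatch: int = 0,
    d_box_window: int = 15,
    min_length: int = 20,
) -> BoxAnnotation:
    """Locate C, D and (optionally) D' boxes.

    The D box is searched within the 3'-terminal ``d_box_window`` nucleotides
    (fewest mismatches, tie broken toward the 3' end); a snoRNA whose terminal
    CUGA is mutated beyond the budget therefore has a *missing* D box and is
    flagged non-canonical even if an internal CUGA exists -- that internal copy
    is reported as the D' box instead. The C box is the best match nearest the
    5' end, upstream of the D box.
    """
    seq = canonical(sequence)
    if len(seq) < min_length:
        raise ValueError(
            f"sequence of length {len(seq)} is below the minimum of {min_length}"
        )
    ann = BoxAnnotation(sequence=seq)

    d_cands = list(
        _candidates(seq, d_box_consensus, d_max_mismatch, len(seq) - d_box_window, len(seq))
    )
    if d_cands:
        start, mm = min(d_cands, key=lambda c: (c[1], -c[0]))
        end = start + len(d_box_consensus)
        ann.d_box = BoxMatch(start, end, seq[start:end], mm)
    else:
        ann.non_canonical = True

    c_limit = ann.d_box.start if ann.d_box else len(seq)
    c_cands = list(_candidates(seq, c_box_consensus, c_max_mismatch, 0, c_limit))
    if c_cands:
        start, mm = min(c_cands, key=lambda c: (c[1], c[0]))
        end = start + len(c_box_consensus)
        ann.c_box = BoxMatch(start, end, seq[start:end], mm)
    else:
        ann.non_canonical = True

    dp_lo = ann.c_box.end if ann.c_box else 0
    dp_hi = ann.d_box.start if ann.d_box else len(seq)
    dp_cands = list(_candidates(seq, d_box_consensus, d_prime_max_mismatch, dp_lo, dp_hi))
    if dp_cands:
        start, mm = min(dp_cands, key=lambda c: (c[1], -c[0]))
        end = start + len(d_box_consensus)
        ann.d_prime_box = BoxMatch(start, end, seq[start:end], mm)
    return ann


def _antisense_match(guide: str, target: str, allow_gu: bool) -> bool:
    """True when the guide pairs perfectly (antiparallel) with some window of
    the target; the guide's 3'-most base pairs the window's first base."""
    pairs = _GU_PAIRS if allow_gu else _WC_PAIRS
    L = len(guide)
    rg = guide[::-1]
    for s in range(len(target) - L + 1):
        window = target[s : s + L]
        if all((g, t) in pairs for g, t in zip(rg, window)):
            return True
    return False


def find_guide(
    sequence: str,
    target_sequence: str | None,
    boxes: BoxAnnotation,
    min_duplex: int = 9,
    allow_gu: bool = True,
    max_duplex: int | None = None,
) -> list[tuple[int, int]]:
    """Guide (antisense) intervals abutting the 5' side of the D and D' boxes.

    For each box, the longest stretch ending at the box's 5' edge that forms a
    perfect antiparallel duplex with the target (G.U wobble allowed by default)
    and is at least ``min_duplex`` nt long is reported. Without a target the
    result is empty. The found intervals are also stored on ``boxes``.
    """
    intervals: list[tuple[int, int]] = []
    if target_sequence:
        seq = canonical(boxes.sequence or sequence)
        target = canonical(target_sequence)
        floor = boxes.c_box.end if boxes.c_box else 0
        for box in (boxes.d_prime_box, boxes.d_box):
            if box is None:
                continue
            longest = box.start - floor
            if max_duplex is not None:
                longest = min(longest, max_duplex)
            for L in range(longest, min_duplex - 1, -1):
                guide = seq[box.start - L : box.start]
                if _antisense_match(guide, target, allow_gu):
                    intervals.append((box.start - L, box.start))
                    break
    intervals.sort()
    boxes.guide_intervals = intervals
    return intervals


@dataclass
class SnpClassification:
    position: int
    ref_base: str
    alt_base: str
    region: str  # C_box | D_box | D_prime_box | guide | other


def classify_snp(
    position: int,
    boxes: BoxAnnotation,
    ref_base: str = "",
    alt_base: str = "",
) -> SnpClassification:
    """Region call for a SNP position: box membership first (boxes take
    precedence over the guide on overlap), then guide, else 'other'
    (functionally silent)."""
    if not 0 <= position < boxes.length:
        raise ValueError(
            f"SNP position {position} outside sequence of length {boxes.length}"
        )
    region = "other"
    named = (
        ("C_box", boxes.c_box),
        ("D_box", boxes.d_box),
        ("D_prime_box", boxes.d_prime_box),
    )
    for name, box in named:
        if box is not None and box.start <= position < box.end:
            region = name
            break
    else:
        for lo, hi in boxes.guide_intervals:
            if lo <= position < hi:
                region = "guide"
                break
    return SnpClassification(
        position=position, ref_base=ref_base, alt_base=alt_base, region=region
    )


def annotation_frame(annotations: dict[str, BoxAnnotation]) -> pd.DataFrame:
    """TSV-ready summary of box/guide intervals per snoRNA id."""

    def fmt(box: BoxMatch | None) -> str:
        return f"{box.start}-{box.end}" if box else ""

    rows = []
    for rid in sorted(annotations):
        ann = annotations[rid]
        rows.append(
            {
                "id": rid,
                "length": ann.length,
                "c_box": fmt(ann.c_box),
                "d_box": fmt(ann.d_box),
                "d_prime_box": fmt(ann.d_prime_box),
                "guides": ";".join(f"{a}-{b}" for a, b in ann.guide_intervals),
                "non_canonical": ann.non_canonical,
            }
        )
    return pd.DataFrame(rows)
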