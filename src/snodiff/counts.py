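"""Unique-sequence tallies per library and reads-per-million normalization.

Identical merged sequences are counted as one *sequence type*; the library's
expression of a type is its count divided by the library's total number of
merged sequences, times 10^6 (rpm). The rpm denominator is the number of merged
RNA sequences, not the number of raw read pairs.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

__all__ = ["CountTable", "RpmTable", "tally", "to_rpm"]


def canonical(seq: str) -> str:
    """Sequence identity used throughout: uppercase, RNA U unified to T."""
    return seq.upper().replace("U", "T")


@dataclass
class CountTable:
    """Per-library tally of identical sequences. ``total`` equals the sum of
    counts and zero-count entries never appear."""

    library_id: str = ""
    strain: str = ""
    counts: dict[str, int] = field(default_factory=dict)
    total: int = 0


@dataclass
class RpmTable:
    library_id: str = ""
    strain: str = ""
    rpm: dict[str, float] = field(default_factory=dict)


def tally(merged: Iterable, library_id: str = "", strain: str = "") -> CountTable:
    """Count identical sequences in a stream of merged RNAs (or plain strings)."""
    counter: Counter[str] = Counter()
    for item in merged:
        seq = getattr(item, "sequence", item)
        counter[canonical(seq)] += 1
    return CountTable(
        library_id=library_id,
        strain=strain,
        counts=dict(counter),
        total=sum(counter.values()),
    )


def to_rpm(table: CountTable) -> RpmTable:
    """counts / total x 10^6; rpm values of a nonempty table sum to 10^6."""
    if table.total <= 0:
        raise ValueError(
            f"library {table.library_id!r}: cannot normalize an empty count table"
        )
    scale = 1e6 / table.total
    return RpmTable(
        library_id=table.library_id,
        strain=table.strain,
        rpm={seq: n * scale for seq, n in table.counts.items()},
    )


def counts_frame(table: CountTable, rpm: RpmTable | None = None) -> pd.DataFrame:
    """TSV-ready frame with columns sequence, count, rpm, library_id, strain."""
    if rpm is None and table.total > 0:
        rpm = to_rpm(table)
    rpm_map: Mapping[str, float] = rpm.rpm if rpm is not None else {}
    rows = sorted(table.counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        {
            "sequence": [s for s, _ in rows],
            "count": [n for _, n in rows],
            "rpm": [rpm_map.get(s, 0.0) for s, _ in rows],
            "library_id": table.library_id,
            "strain": table.strain,
        }
    )


def write_counts_tsv(table: CountTable, path) -> None:
    counts_frame(table).to_csv(path, sep="\t", index=False)


def read_counts_tsv(path) -> CountTable:
    df = pd.read_csv(path, sep="\t", dtype={"sequence": str})
    library_id = str(df["library_id"].iloc[0]) if len(df) else ""
    strain = str(df["strain"].iloc[0]) if len(df) else ""
    counts = {canonical(s): int(n) for s, n in zip(df["sequence"], df["count"])}
    return CountTable(
        library_id=library_id, strain=strain, counts=counts, total=sum(counts.values())
    )
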