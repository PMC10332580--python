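"""Synthetic two-strain small-RNA libraries with known ground truth.

The generator builds a pair of strain genomes-in-miniature: a set of box C/D
snoRNA loci for a reference strain (B6) and a derived strain (MSM) that differ
only at planted SNPs. Each locus carries a C box (RTGATGA), an internal D' box
(CTGA), a D box (CTGA) near the 3' end and an antisense guide element flush
against the D box that is a perfect reverse complement of a window of a shared
target RNA. A configurable subset of loci carries 1..max SNPs, placed in a box,
in the guide, or in spacer regions ("other"); one locus can be silenced in one
strain, carrying a SNP at the first base of its D box in the silenced strain --
the pattern shown by SNORD53, which is expressed in MSM only and whose B6
allele has a mutated CUGA box.

Libraries emulate 151-nt paired-end sequencing of gel-purified 40-140 nt small
RNAs prepared with three library kits: each fragment is a locus substring with
up to ``end_jitter`` nt trimmed independently from each end, read 1 runs
through the insert into the 3' adapter, read 2 reads the reverse complement and
its own adapter, per-base substitution errors are applied, and a small fraction
of fragments is drawn from the *other* strain's loci (cross-strain
contamination during sample/library preparation). All randomness derives from
a single seed; runs are bit-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import yaml

from .merge import _open_text, reverse_complement

__all__ = [
    "SnoLocus",
    "StrainPairTruth",
    "SimConfig",
    "ReadPair",
    "FragmentRecord",
    "build_strain_pair",
    "simulate_library",
    "write_library",
    "write_truth",
]

Interval = tuple[int, int]

_BASES = "ACGT"
# first 3' adapter seen by read 1 (TruSeq small-RNA RA3) and the reverse
# complement of the 5' adapter seen by read 2 after the insert
DEFAULT_ADAPTER_R1 = "TGGAATTCTCGGGTGCCAAGGAACTCCAGTCAC"
DEFAULT_ADAPTER_R2 = "GATCGTCGGACTGTAGAACTCTGAAC"

_PAIRS_GU = {("A", "T"), ("T", "A"), ("G", "C"), ("C", "G"), ("G", "T"), ("T", "G")}


@dataclass
class SnoLocus:
    """One snoRNA locus on the sense strand, with its element intervals
    (0-based, half-open)."""

    id: str
    sequence: str
    c_box: Interval
    d_box: Interval
    d_prime_box: Interval | None = None
    guide: Interval | None = None
    host_gene: str | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class SimConfig:
    """Study conditions for the simulator; the defaults mirror the emulated
    experiment (three 151-nt paired-end library preparations per strain of
    gel-purified 40-140 nt brain small RNAs)."""

    n_loci: int = 20
    locus_length: tuple[int, int] = (70, 140)
    insert_range: tuple[int, int] = (40, 140)
    read_length: int = 151
    n_libraries: int = 3
    depth_mean: float = 5000.0
    depth_sigma: float = 0.35  # lognormal spread of per-locus depth
    error_rate: float = 0.001
    contamination_rate: float = 0.001
    end_jitter: int = 3
    n_snp_loci: int = 5
    max_snps_per_locus: int = 4
    n_box_snp_loci: int = 1
    n_guide_snp_loci: int = 1
    n_silenced: int = 1
    silenced_strain: str = "B6"
    guide_length: int = 12
    target_length: int = 200
    min_overlap: int = 10
    adapter_3p_r1: str = DEFAULT_ADAPTER_R1
    adapter_3p_r2: str = DEFAULT_ADAPTER_R2
    seed: int = 0

    def validate(self) -> None:
        if self.n_loci < 0 or self.n_libraries < 1:
            raise ValueError("n_loci must be >= 0 and n_libraries >= 1")
        for rate in (self.error_rate, self.contamination_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.insert_range[1] > 2 * self.read_length - self.min_overlap:
            raise ValueError(
                "insert maximum exceeds 2 x read_length - min_overlap; such "
                "inserts cannot be reconstructed by overlap"
            )
        if not (
            self.insert_range[0]
            <= self.locus_length[0] - 2 * self.end_jitter
            and self.locus_length[1] <= self.insert_range[1]
        ):
            raise ValueError("locus_length with end_jitter must fit insert_range")
        min_len = 27 + self.guide_length + self.max_snps_per_locus + 4
        if self.locus_length[0] < min_len:
            raise ValueError(
                f"locus too short to place C box, guide, D box: need at least "
                f"{min_len} nt, got locus_length minimum {self.locus_length[0]}"
            )
        if self.n_snp_loci + self.n_silenced > self.n_loci:
            raise ValueError("more SNP/silenced loci requested than loci")
        if self.n_box_snp_loci + self.n_guide_snp_loci > max(self.n_snp_loci, 0):
            raise ValueError("box+guide SNP loci exceed n_snp_loci")
        if self.silenced_strain not in ("B6", "MSM"):
            raise ValueError("silenced_strain must be B6 or MSM")


@dataclass
class StrainPairTruth:
    """Ground truth: the two strains' loci (same ids), planted SNPs with their
    region labels, per-strain expected fragment depth, silencing flags and the
    shared target RNA."""

    loci_b6: dict[str, SnoLocus]
    loci_msm: dict[str, SnoLocus]
    snps: dict[str, list[tuple[int, str, str]]]  # id -> [(pos, base_b6, base_msm)]
    snp_regions: dict[str, list[str]]  # parallel region labels
    expression: dict[str, dict[str, int]]  # id -> {"B6": depth, "MSM": depth}
    silenced: dict[str, str | None]  # id -> strain silenced in, or None
    target: str

    @property
    def differential_ids(self) -> set[str]:
        """Loci whose read patterns should separate the strains (planted SNPs
        and/or silencing)."""
        return {i for i, s in self.snps.items() if s} | {
            i for i, s in self.silenced.items() if s
        }


@dataclass
class ReadPair:
    id: str
    seq1: str
    seq2: str
    qual1: str
    qual2: str


@dataclass
class FragmentRecord:
    """Manifest row: where a simulated fragment came from."""

    pair_id: str
    locus_id: str
    source_strain: str
    contaminant: bool
    insert: str


def _random_seq(rng: np.random.Generator, n: int) -> list[str]:
    return [_BASES[i] for i in rng.integers(0, 4, n)]


def _motif_starts(seq: str, motifs: tuple[str, ...]) -> set[int]:
    out: set[int] = set()
    for motif in motifs:
        pos = seq.find(motif)
        while pos != -1:
            out.add(pos)
            pos = seq.find(motif, pos + 1)
    return out


def _clean(seq: str, d_starts: set[int], c_start: int) -> bool:
    """No exact box motifs besides the planted ones (planted ones may have
    been destroyed by a SNP, hence subset)."""
    return _motif_starts(seq, ("CTGA",)) <= d_starts and _motif_starts(
        seq, ("ATGATGA", "GTGATGA")
    ) <= ({c_start} if c_start >= 0 else set())


def _build_locus(
    rng: np.random.Generator, locus_id: str, length: int, target: str, guide_len: int
) -> SnoLocus:
    """One canonical locus; retries until the only exact box motifs are the
    planted ones and the guide cannot extend past its planted 5' edge."""
    c_box = (4, 11)
    d_prime = (14, 18)
    d_box = (length - 8, length - 4)
    g0 = d_box[0] - guide_len
    for _ in range(500):
        chars = _random_seq(rng, length)
        chars[4:11] = ("A" if rng.integers(0, 2) else "G") + "TGATGA"
        chars[14:18] = "CTGA"
        chars[d_box[0] : d_box[1]] = "CTGA"
        s = int(rng.integers(0, len(target) - guide_len + 1))
        window = target[s : s + guide_len]
        chars[g0 : d_box[0]] = reverse_complement(window)
        # block 5'-extension of the guide: the base before it must not pair
        # (even by G.U wobble) with the target base following the window
        if s + guide_len < len(target):
            nxt = target[s + guide_len]
            blocked = [b for b in _BASES if (b, nxt) not in _PAIRS_GU]
            chars[g0 - 1] = blocked[rng.integers(0, len(blocked))]
        seq = "".join(chars)
        if _clean(seq, {d_prime[0], d_box[0]}, 4):
            return SnoLocus(
                id=locus_id,
                sequence=seq,
                c_box=c_box,
                d_box=d_box,
                d_prime_box=d_prime,
                guide=(g0, d_box[0]),
            )
    raise RuntimeError(f"could not build a motif-clean locus of length {length}")


def _region_of(pos: int, locus: SnoLocus) -> str:
    for name, iv in (
        ("C_box", locus.c_box),
        ("D_box", locus.d_box),
        ("D_prime_box", locus.d_prime_box),
    ):
        if iv and iv[0] <= pos < iv[1]:
            return name
    if locus.guide and locus.guide[0] <= pos < locus.guide[1]:
        return "guide"
    return "other"


def _plant_snps(
    rng: np.random.Generator,
    locus: SnoLocus,
    n_snps: int,
    first_region: str,
) -> tuple[str, list[tuple[int, str, str]]]:
    """Derived (MSM) sequence and the SNP list (pos, ref_base, alt_base).

    ``first_region`` places the first SNP: 'D_box' at the first base of the D
    box (C -> T, the box-killing mutation), 'guide' mid-guide, 'other' in a
    spacer. Remaining SNPs go to spacers. Redraws until the derived sequence
    gains no new exact box motifs.
    """
    length = locus.length
    g0, d0 = locus.guide[0], locus.d_box[0]
    free = [
        p
        for p in range(19, g0 - 1)
        if not (locus.d_prime_box[0] <= p < locus.d_prime_box[1])
    ]
    for _ in range(200):
        positions: list[int] = []
        if first_region == "D_box":
            positions.append(d0)
        elif first_region == "guide":
            positions.append(g0 + (d0 - g0) // 2)
        n_free = n_snps - len(positions)
        idx = rng.choice(len(free), size=n_free, replace=False)
        positions.extend(free[int(i)] for i in idx)
        positions = sorted(set(positions))
        if len(positions) != n_snps:
            continue
        chars = list(locus.sequence)
        snps: list[tuple[int, str, str]] = []
        for pos in positions:
            ref = chars[pos]
            if pos == d0 and first_region == "D_box":
                alt = "T"
            else:
                alts = [b for b in _BASES if b != ref]
                alt = alts[rng.integers(0, 3)]
            chars[pos] = alt
            snps.append((pos, ref, alt))
        derived = "".join(chars)
        planted_d = {locus.d_prime_box[0], d0}
        if _clean(derived, planted_d, locus.c_box[0]):
            return derived, snps
    raise RuntimeError(f"could not plant {n_snps} clean SNPs in {locus.id}")


def build_strain_pair(config: SimConfig) -> StrainPairTruth:
    """Generate the two strains' loci and the full ground truth.

    Locus roles are assigned in id order: ``n_snp_loci`` loci expressed in both
    strains with planted SNPs (the first ``n_box_snp_loci`` with a D-box SNP,
    the next ``n_guide_snp_loci`` with a guide SNP, the rest in spacers), then
    ``n_silenced`` loci silenced in ``silenced_strain`` with the box-killing
    SNP in that strain, then neutral loci identical between strains.
    """
    config.validate()
    rng = np.random.default_rng(int(config.seed))
    target = "".join(_random_seq(rng, config.target_length))

    loci_b6: dict[str, SnoLocus] = {}
    loci_msm: dict[str, SnoLocus] = {}
    snps: dict[str, list[tuple[int, str, str]]] = {}
    regions: dict[str, list[str]] = {}
    expression: dict[str, dict[str, int]] = {}
    silenced: dict[str, str | None] = {}

    for i in range(config.n_loci):
        locus_id = f"SNO{i + 1:03d}"
        length = int(rng.integers(config.locus_length[0], config.locus_length[1] + 1))
        base = _build_locus(rng, locus_id, length, target, config.guide_length)
        if config.depth_sigma > 0:
            depth = int(round(config.depth_mean * np.exp(rng.normal(0.0, config.depth_sigma))))
        else:
            depth = int(round(config.depth_mean))
        depth = max(depth, 1)
        expr = {"B6": depth, "MSM": depth}
        locus_snps: list[tuple[int, str, str]] = []
        b6_seq = base.sequence
        msm_seq = base.sequence
        silenced_in: str | None = None

        if i < config.n_snp_loci:
            if i < config.n_box_snp_loci:
                first = "D_box"
            elif i < config.n_box_snp_loci + config.n_guide_snp_loci:
                first = "guide"
            else:
                first = "other"
            n_snps = 1 + (i % config.max_snps_per_locus)
            msm_seq, locus_snps = _plant_snps(rng, base, n_snps, first)
        elif i < config.n_snp_loci + config.n_silenced:
            # box-killing SNP carried by the silenced strain
            mutated, box_snp = _plant_snps(rng, base, 1, "D_box")
            silenced_in = config.silenced_strain
            expr[silenced_in] = 0
            pos, intact, mutated_base = box_snp[0]
            if silenced_in == "B6":
                b6_seq = mutated
                locus_snps = [(pos, mutated_base, intact)]
            else:
                msm_seq = mutated
                locus_snps = [(pos, intact, mutated_base)]

        loci_b6[locus_id] = dataclasses.replace(base, sequence=b6_seq)
        loci_msm[locus_id] = dataclasses.replace(base, sequence=msm_seq)
        snps[locus_id] = locus_snps
        regions[locus_id] = [_region_of(p, base) for p, _, _ in locus_snps]
        expression[locus_id] = expr
        silenced[locus_id] = silenced_in

    return StrainPairTruth(
        loci_b6=loci_b6,
        loci_msm=loci_msm,
        snps=snps,
        snp_regions=regions,
        expression=expression,
        silenced=silenced,
        target=target,
    )


def _mutate(seq: str, n_err: int, rng: np.random.Generator) -> str:
    if n_err <= 0:
        return seq
    chars = list(seq)
    for p in rng.choice(len(chars), size=min(n_err, len(chars)), replace=False):
        alts = [b for b in _BASES if b != chars[p]]
        chars[p] = alts[rng.integers(0, len(alts))]
    return "".join(chars)


def _make_read(insert: str, adapter: str, read_length: int) -> str:
    read = insert + adapter
    if len(read) < read_length:
        read += "A" * (read_length - len(read))
    return read[:read_length]


def simulate_library(
    truth: StrainPairTruth,
    strain: str,
    library_index: int,
    config: SimConfig,
) -> Iterator[tuple[ReadPair, FragmentRecord]]:
    """Simulate one strain's library for one preparation ("analysis").

    Yields (read pair, manifest record). Native fragments are drawn per locus
    at its planted depth; with probability ``contamination_rate`` a fragment is
    replaced by one drawn (expression-weighted) from the other strain's loci.
    Silenced loci yield no native fragments.
    """
    if strain not in ("B6", "MSM"):
        raise ValueError(f"strain must be B6 or MSM, got {strain!r}")
    if not 0 <= library_index < config.n_libraries:
        raise ValueError(f"library_index {library_index} >= n_libraries")
    other = "MSM" if strain == "B6" else "B6"
    rng = np.random.default_rng(
        [int(config.seed), 1 + library_index, 1 if strain == "B6" else 2]
    )
    loci = truth.loci_b6 if strain == "B6" else truth.loci_msm
    other_loci = truth.loci_msm if strain == "B6" else truth.loci_b6

    other_ids = sorted(i for i in other_loci if truth.expression[i][other] > 0)
    weights = np.array(
        [truth.expression[i][other] for i in other_ids], dtype=float
    )
    cum = np.cumsum(weights) / weights.sum() if len(other_ids) else None

    qual = "I" * config.read_length
    jmax = config.end_jitter
    counter = 0
    for locus_id in sorted(loci):
        depth = truth.expression[locus_id][strain]
        for _ in range(depth):
            counter += 1
            contaminant = bool(
                config.contamination_rate > 0
                and cum is not None
                and rng.random() < config.contamination_rate
            )
            if contaminant:
                src = other_ids[int(np.searchsorted(cum, rng.random(), side="right"))]
                source = other_loci[src]
                src_strain = other
            else:
                source = loci[locus_id]
                src_strain = strain
            t5, t3 = (rng.integers(0, jmax + 1, 2) if jmax else (0, 0))
            insert = source.sequence[int(t5) : source.length - int(t3)]
            seq1 = _make_read(insert, config.adapter_3p_r1, config.read_length)
            seq2 = _make_read(
                reverse_complement(insert), config.adapter_3p_r2, config.read_length
            )
            if config.error_rate > 0:
                n1, n2 = rng.binomial(config.read_length, config.error_rate, 2)
                seq1 = _mutate(seq1, int(n1), rng)
                seq2 = _mutate(seq2, int(n2), rng)
            pair_id = f"{strain}.lib{library_index + 1}.{counter}"
            yield (
                ReadPair(id=pair_id, seq1=seq1, seq2=seq2, qual1=qual, qual2=qual),
                FragmentRecord(
                    pair_id=pair_id,
                    locus_id=source.id,
                    source_strain=src_strain,
                    contaminant=contaminant,
                    insert=insert,
                ),
            )


def write_library(
    truth: StrainPairTruth,
    strain: str,
    library_index: int,
    config: SimConfig,
    outdir,
    gzip_fastq: bool = False,
) -> dict[str, Path]:
    """Write <strain>_lib<k>_R1/R2.fastq[.gz] plus the fragment manifest TSV;
    returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    suffix = ".fastq.gz" if gzip_fastq else ".fastq"
    stem = f"{strain}_lib{library_index + 1}"
    p1 = outdir / f"{stem}_R1{suffix}"
    p2 = outdir / f"{stem}_R2{suffix}"
    pm = outdir / f"{stem}_manifest.tsv"
    with _open_text(p1, "wt") as h1, _open_text(p2, "wt") as h2, open(pm, "w") as hm:
        hm.write("pair_id\tlocus_id\tsource_strain\tcontaminant\tinsert\n")
        for pair, rec in simulate_library(truth, strain, library_index, config):
            h1.write(f"@{pair.id}/1\n{pair.seq1}\n+\n{pair.qual1}\n")
            h2.write(f"@{pair.id}/2\n{pair.seq2}\n+\n{pair.qual2}\n")
            hm.write(
                f"{rec.pair_id}\t{rec.locus_id}\t{rec.source_strain}\t"
                f"{int(rec.contaminant)}\t{rec.insert}\n"
            )
    return {"r1": p1, "r2": p2, "manifest": pm}


def _interval_str(iv: Interval | None) -> str:
    return f"{iv[0]}-{iv[1]}" if iv else ""


def write_truth(truth: StrainPairTruth, config: SimConfig, outdir) -> dict[str, Path]:
    """Write references (FASTA per strain), the target RNA, the SNP table, the
    locus/annotation table and the config; returns the paths."""
    from Bio.Seq import Seq
    from Bio.SeqIO import write as seqio_write
    from Bio.SeqRecord import SeqRecord

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    for name, loci in (("references_b6", truth.loci_b6), ("references_msm", truth.loci_msm)):
        path = outdir / f"{name}.fasta"
        records = [
            SeqRecord(Seq(loci[i].sequence), id=i, description="") for i in sorted(loci)
        ]
        seqio_write(records, str(path), "fasta")
        paths[name] = path
    target_path = outdir / "target_rna.fasta"
    seqio_write(
        [SeqRecord(Seq(truth.target), id="target", description="")],
        str(target_path),
        "fasta",
    )
    paths["target"] = target_path

    snp_rows = []
    for locus_id in sorted(truth.snps):
        for (pos, b6, msm), region in zip(
            truth.snps[locus_id], truth.snp_regions[locus_id]
        ):
            snp_rows.append(
                {"locus_id": locus_id, "position": pos, "base_b6": b6,
                 "base_msm": msm, "region": region}
            )
    snp_path = outdir / "truth_snps.tsv"
    pd.DataFrame(
        snp_rows, columns=["locus_id", "position", "base_b6", "base_msm", "region"]
    ).to_csv(snp_path, sep="\t", index=False)
    paths["snps"] = snp_path

    loci_rows = []
    for locus_id in sorted(truth.loci_b6):
        loc = truth.loci_b6[locus_id]
        loci_rows.append(
            {
                "locus_id": locus_id,
                "length": loc.length,
                "c_box": _interval_str(loc.c_box),
                "d_prime_box": _interval_str(loc.d_prime_box),
                "guide": _interval_str(loc.guide),
                "d_box": _interval_str(loc.d_box),
                "expression_b6": truth.expression[locus_id]["B6"],
                "expression_msm": truth.expression[locus_id]["MSM"],
                "silenced_in": truth.silenced[locus_id] or "",
            }
        )
    loci_path = outdir / "truth_loci.tsv"
    pd.DataFrame(loci_rows).to_csv(loci_path, sep="\t", index=False)
    paths["loci"] = loci_path

    cfg_path = outdir / "sim_config.yaml"
    with open(cfg_path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)
    paths["config"] = cfg_path
    return paths
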