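# Methods

## Overlap merging

A small-RNA insert of length `n` sequenced 151 nt paired-end is covered by
read 1 from its 5′ end and by read 2 (opposite strand) from its 3′ end. After
reverse-complementing read 2, every relative placement `d` of read 1 against it
is considered; the doubly covered window has length `151 − |d|` and the insert
is always the stretch from the start of read 1 to the end of
reverse-complemented read 2 (`151 − d` nt): for `n > 151` the reads overlap in
the middle, for `n < 151` both reads run through the insert into their ligation
adapters and the single-covered flanks *are* the adapters, which are discarded.
Adapter trimming therefore needs no adapter sequence.

A placement is valid when the window is at least `min_overlap` (default 10) nt
and its mismatch fraction is at most `max_mismatch_frac`. The default is 0
(exact agreement): the analysis lives and dies on single-nucleotide
differences between alleles, and exactness guarantees that a kept insert is an
error-free consensus of both reads over the window. The cost is that a
sequencing error inside the window discards the pair (≈ 18% of pairs at 0.1%
per-base error and ~100-nt inserts), which lowers depth without biasing
strain ratios; the tolerance is configurable for noisier data. Among valid
placements the one with the most matching bases wins; a tie rejects the pair
rather than risking a chimeric insert. Where mismatches are allowed, the
read-1 base is reported (deterministic and quality-agnostic; the pipeline
never uses quality strings). N counts neither as match nor mismatch, and
N-containing inserts are flagged.

Implementation note: with exact matching the overlap is a prefix/suffix match
between the two sequences, so candidates are anchored with a short seed
(`min(12, min_overlap)` nt) and verified by direct slice comparison; the
mismatch-tolerant path scores every offset with vectorized comparisons. Both
paths are checked in the tests against an independent exhaustive-offset scorer.
With 151-nt reads and a 10-nt minimum overlap no merged sequence can exceed
2·151 − 10 = 292 nt; kept lengths default to the closed interval [10, 292].

## Counting and normalization

Identical merged sequences (uppercased, U→T) form one *sequence type*.
Expression is reads per million: rpm(s) = count(s)/total × 10⁶, where the
denominator is the library's number of merged RNA sequences in the kept length
range — not the number of raw read pairs — so rpm values per library sum to
10⁶ by construction.

## Differential selection and categories

Per analysis (one library preparation per strain), a type is selected when
both strains express it and the larger rpm exceeds the smaller by strictly
more than `fold_threshold` (default 100), or when one strain's rpm is zero and
the other's is at least `only_threshold` (default 100 rpm). "More than
100-fold" is implemented strictly (>), while the one-strain-only bound is
inclusive (≥ 100), consistent with category 3's lower bound; both are flags.
No pseudocounts are used — the zero case has its own rule, so ratios are only
formed between positive values. One-strain-only types are binned by rpm into
half-open categories 1–4 at boundaries 10/100/1000 (boundaries fall in the
upper bin). No statistical test is attached to the selection: the rule is a
deterministic threshold on normalized counts, as in the emulated analysis.

## Collapsing fragments and the common set

snoRNA processing and degradation produce fragments of one snoRNA with ragged
5′/3′ ends, so one locus yields many selected sequence types. With reference
snoRNA sequences available (one FASTA per strain, shared ids), each selected
sequence joins the reference containing it as an exact substring; sequences
matching no reference exactly are placed by fewest substitutions over all
ungapped full placements (budget `max_substitutions`, default 4). A sequence
matching several references equally well is flagged ambiguous and left
ungrouped rather than guessed. Without references, sequences are grouped by
transitive substring containment. Group totals are rpm sums over members, so
collapsing conserves rpm mass (up to explicitly reported ungrouped
sequences). The ids of groups selected in *every* analysis form the common
set; intersecting at the snoRNA (reference-id) level rather than the exact
sequence level tolerates per-kit differences in end processing.

## Allele pairing and SNP counting

Alignment is ungapped throughout: alleles of one snoRNA differ by
substitutions, and indel alleles are out of scope (they are reported
unalignable). `best_ungapped_offset` slides one sequence along the other,
maximizes matching bases in the overlap, and breaks ties by smaller |offset|,
then negative offset first. The SNP count of a pair is the Hamming distance of
the overlap at that offset.

Strain-biased groups (each represented by its highest-support member) are
paired as mutual best matches with at most `max_snp` (default 4)
substitutions; mutual-best matching makes pairing symmetric under swapping the
strains. Ties — near-identical copies of clustered snoRNAs (SNORD115/116-like)
— produce one pair per tied counterpart, flagged ambiguous, rather than
forcing a bijection. Groups without a counterpart are reported as
strain-exclusive, the signature of a locus silenced (or degraded) in one
strain. Each type carries its read support in *both* strains' libraries, so
low cross-counts of an allele in the other strain — library cross-contamination
— stay visible in the output. SNP positions are additionally reported against
the reference sequence (`snps_vs_reference`, reference coordinates), since a
pair's internal coordinates and the genome's may differ by end trimming.

## Box and guide annotation

Consensi follow the standard box C/D literature and are configurable: C box
RTGATGA with ≤ 1 mismatch, D and D′ box CTGA exact. The D box must lie within
the 3′-terminal window (`d_box_window`, default 15 nt): a snoRNA whose
terminal CUGA is destroyed by a mutation is annotated as *missing* its D box
and flagged non-canonical — the internal intact CUGA is then reported as the
D′ box, not promoted to D. This positional constraint is what lets the
pipeline flag a SNORD53-like allele (terminal box mutated in one strain) while
still annotating its internal box. Within the window the fewest-mismatch match
wins, ties toward the 3′ end; the C box takes the fewest-mismatch match
nearest the 5′ end upstream of the D box.

The guide element is the longest stretch ending flush at the 5′ edge of the
D (or D′) box that forms a perfect antiparallel duplex of ≥ `min_duplex`
(default 9) nt with the supplied target RNA; G·U wobble counts as pairing by
default (both knobs exposed). Without a target, guide annotation is empty, not
an error. SNP classification is pure interval membership with box-over-guide
precedence; positions outside all elements are "other" (functionally silent).
When one allele's box is destroyed by the SNP itself, classification uses the
annotation of the allele whose D box is intact. Coordinates are 0-based
half-open everywhere; sequences are DNA internally (U→T).

## Simulator

The generator emulates the study conditions: two strains' snoRNA loci
(defaults: 20 loci of 70–140 nt, within the 40–140 nt gel-purified insert
range), three independently seeded 151-nt paired-end libraries per strain
(the three preparation kits are modeled only as independent samplings, not as
distinct chemistries), per-locus depth (default mean 5000 fragments; a
lognormal spread with σ = 0.35 is the default since real snoRNA expression
varies, and can be set to 0 for constant depth), 5′/3′ end jitter (uniform
0–3 nt, trimming only), adapter read-through using the TruSeq small-RNA
adapter sequences (configurable), per-base substitution errors (default
0.1%), and cross-strain contamination (default 0.1% of fragments drawn from
the other strain, expression-weighted) — reproducing the pattern of large
native counts against tens of contaminant reads. Quality strings are constant
high quality; nothing downstream reads them.

Ground truth is explicit: per-locus SNP positions with region labels, per
strain expression, and silencing flags. Locus roles are deterministic given
the config: `n_snp_loci` loci carry 1 + (i mod `max_snps_per_locus`) SNPs,
with configurable counts placed at the first base of the D box (the
box-killing C→U mutation) or mid-guide, the rest in spacers at least 10 nt
from either end so every jittered fragment still carries them; `n_silenced`
loci are unexpressed in one strain and carry the box-killing SNP in that
strain's genome. Loci are re-sampled until the only exact box motifs are the
planted ones and the guide cannot extend past its planted 5′ edge, making
box/guide recovery exactly decidable. All randomness flows from one seed
(truth from the seed; each library from seed + strain + library index), so
runs are byte-reproducible.

What the simulator does **not** model: ligation/capture bias differences among
kits, PCR duplicates, indels, quality-dependent errors, true snoRNA secondary
structure, or a genomic background beyond the snoRNA loci. Passing the
parameter-recovery suite therefore shows the pipeline's logic is correct under
controlled noise, not that real libraries are this clean — in real data the
reference matching, mismatch tolerance and thresholds carry more weight.

## Validation scale and numerical choices

The parameter-recovery suite runs the defaults-scale study: 20 loci (5 SNP
loci, 1 silenced-in-B6 locus with a box mutation, 14 neutral), constant depth
5000 per locus, 3 libraries per strain, 0.1% error, 0.1% contamination —
about 585,000 read pairs end to end — and requires the common set to equal the
6 planted differential loci exactly, allele pairs to recover every planted SNP
count, the silenced locus to come out strain-exclusive, and every planted SNP
region label to be re-derived from sequence alone. The merge oracle check runs
the fast merger against an exhaustive-offset brute force on > 1000 simulated
151-nt pairs. Degenerate inputs are defined, not special-cased: empty
libraries produce empty but well-formed outputs, an empty count table cannot
be rpm-normalized (error), and out-of-range positions or negative rpm raise.

## Known limitations

- Ungapped alignment only: indel alleles surface as unalignable/exclusive.
- Reference matching replaces genome mapping; sequences absent from the
  supplied reference FASTA (beyond the substitution budget) stay ungrouped.
- H/ACA (SNORA) snoRNAs, methylation-site prediction (fifth-nucleotide rule)
  and secondary structure are out of scope.
- The rpm denominator is merged sequences, not raw read pairs; comparisons
  with pipelines normalizing by raw reads will differ by a few percent.
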