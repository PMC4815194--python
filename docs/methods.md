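# Methods

This note documents the models and procedures implemented in adnapipe, the
parameters that matter, the numerical choices made where the design was
genuinely open, and what the simulator does and does not emulate.

## Adapter clipping

Adapter hits are found by local alignment between read and adapter with
match +1, mismatch −1 and an effective gap penalty of −5; because adapter
contamination is ungapped in practice, candidates are enumerated gaplessly
(a gapped hit would always score below its best gapless sub-segment at
these penalties). A candidate qualifies when its length is at least
`min_adapter_overlap` (default 8) with at most `max_adapter_mismatches`
(default 1) mismatches, and it is *anchored*: it either reaches the read's
3′ end (partial adapter at the end of the read) or starts at adapter
position 0 (the full adapter beginning inside the read, i.e. read-through).
Among qualifying candidates the highest score wins; ties prefer the longer
hit, then the smaller clip point. If the accepted alignment starts at
adapter position *a* > 0, the clip point is shifted 5′-ward by *a* bases so
that no adapter prefix can survive in the read. Clipping removes everything
from the (shifted) alignment start to the read end; a clip point of 0
yields an empty read that the driver discards.

False positives: on adapter-free reads, a chance 8-mer with ≤1 mismatch
occurs at a given position with probability ≈ 3.8 × 10⁻⁴, so a few percent
of long-insert reads lose a short 3′ tail. This mirrors the behaviour of
standard trimmers at comparable minimum-overlap settings; raising
`min_adapter_overlap` lowers the rate. On reads that truly carry ≥ 8
adapter bases the genuine hit's score dominates all chance hits, so
clipping is exact there.

## Overlap merging

The reverse mate is reverse-complemented and overlaps between the forward
read's suffix and its prefix are examined in strictly decreasing length,
from min(|F|, |R̄|) down to `min_merge_overlap` (default 10). An overlap of
length ℓ is accepted iff its mismatch count d satisfies d < ⌈f·ℓ⌉ with
f = `max_overlap_edit_fraction` (default 0.05, strict inequality); a
zero-mismatch overlap is always acceptable, so f = 0 means "exact match
required" rather than "never merge". Bases with quality below
`low_quality_cutoff` (default 20), and `N`s, are undefined and never count
toward d. An absolute mismatch budget (`max_overlap_edits`) is available as
an alternative to the fraction. The first acceptable overlap is therefore
the maximal one. Consensus per overlap column: the higher-quality base,
quality max(q_F, q_R), quality ties resolved to the forward base — a
deterministic, conservative rule (no quality summation that could
overstate certainty). Only suffix(F)↔prefix(R̄) overlaps are considered;
dovetail geometries where R̄ extends 5′ of F after clipping are not merged
and are noted as a limitation. Unmerged mates are 3′-quality-trimmed
(longest suffix below `trim_quality`, default 20); any read or merged
product shorter than `min_read_length` (default 25) discards the pair, since
unmerged outputs must remain record-synchronised.

## Circular-reference rewriting

A circular target of length L is elongated by its first k bases (default
500; k should be at least the longest read, and 1 ≤ k ≤ L). After external
mapping against the elongated sequence, records on the target are
partitioned with precedence junction > edge > interior, which turns the
naturally overlapping interval definitions into a partition:

* junction: pos ≤ L < end — split after L − pos + 1 reference bases. The
  left part keeps the original position; the right part starts at position
  1 (+ any deleted reference bases at the junction), carries the
  supplementary flag (0x800), and both carry a shared `XJ` tag. An
  insertion or soft clip falling exactly on the boundary stays with the
  left part (it consumes no reference); a deletion reaching past the
  boundary is converted into a start offset of the right record, the only
  representation that avoids an illegal leading-deletion CIGAR — the event
  is counted.
* edge: wholly inside the first k bases (unchanged) or wholly inside the
  elongation window (translated by −L). The elongation copy is by
  construction byte-identical to the genome start, so the translation is
  exact and no re-mapping is needed. A MAPQ of 0 on an edge record is
  interpreted as the mapper's reaction to the artificial duplication and
  restored to `restored_mapq` (default 37, configurable — the appropriate
  value depends on the mapper's scale, so it is a flag rather than a
  guess).
* interior: untouched.

The output header advertises length L, coordinate order is re-established,
and the whole-file driver checks that every output record ends at or
before L. Mate fields of split paired records are left untouched (merged
reads are single-ended, so the case is marginal) and the count is logged.
Exactly one circular target per run is supported; in a multi-sequence
reference only the named target is elongated, which also covers the
nuclear-mitochondrial (NUMT) use case of mapping against a whole genome
while treating only the mitochondrion as circular.

## Duplicate removal

Merged reads key on (reference, start, end, strand); unmerged reads on the
strand's 5′ coordinate only. Strand is part of the merged key — two
reverse-complementary molecules with mirrored coordinates are distinct
fragments — which is stricter than keying on coordinates alone. Within a
key group the record with the maximal base-quality sum survives (missing
qualities count 0; ties keep the first record in file order, deterministic
under the required coordinate sort). Merged-ness is read from the
`M_` read-id prefix the merger emits, overridable with all-merged /
all-unmerged policies. Unmapped, secondary and supplementary records pass
through unexamined. The sweep is windowed: a group closes once the sweep
position passes its closing coordinate (start for both-end and forward 5′
keys, end for reverse 5′ keys), so memory is bounded by the local pile-up.
The output preserves input order (a coordinate-sorted input therefore
stays sorted). Note that fragments indistinguishable by endpoints are
merged by construction — on dense data the kept count equals the number of
distinct (start, end, strand) triples, not the number of molecules.

## Draft-genome construction

Sites are classified by a cascade at thresholds `min_qual` (30),
`min_depth` (5) and `min_fraction` (0.90), all configurable:

1. confident SNP: qual ≥ 30 ∧ alt-supporting reads ≥ 5 ∧ alt fraction ≥ 0.9;
2. else confident reference: qual ≥ 30 ∧ ref-supporting reads ≥ 5 ∧ ref
   fraction ≥ 0.9;
3. else weak SNP: qual ≥ 30 ∧ alt fraction ≥ 0.9 (support below 5);
4. else weak reference: qual ≥ 30 ∧ the reference allele is major
   (ties to reference) — the class covering reference-major sites that
   fail support or fraction;
5. else no call (including quality failures and zero usable reads).

Fractions use supporting-read counts (sample `AD`, falling back to INFO
`DP4`); when exactly one read supports the minor allele the major allele is
treated as 100 %-confirmed, damping `N` inflation from stray errors at low
coverage. The rule lifts only the strict major (a 1-vs-1 site lifts the
reference, by the tie rule). Depth gates use allele-supporting counts on
both branches. Indel rows are skipped (drafts must keep reference
coordinates) and counted; at multi-allelic sites the best-supported alt is
evaluated. Positions absent from the VCF are no-calls — an all-sites VCF
is the expected input, and a warning fires when more than half the genome
is absent. Three drafts of exact reference length are emitted: strict
(`N` at non-calls), reference-filled (reference base wherever strict has
`N`), and uncertainty-encoded (lowercase alt for weak SNPs, `R` for weak
reference calls, `N` otherwise). Raising any threshold can only turn
called bases into `N`, never the reverse.

Fraction comparisons are plain double comparisons; counts like 18/20
evaluate to the same double as the 0.90 threshold, so "at least 90 %" holds
exactly at the boundary.

## Simulator

The generator emulates the aDNA features the stages exist for: fragment
lengths lognormal with configurable mean/sd (default mean 60 bp, sd 15,
truncated to [20, 500] — the short end of observed ancient libraries;
uniform and fixed-length modes exist for controlled experiments), uniform
fragment placement with origin wrap-around on circular genomes, PCR copies
(a fragment gains 1 + Geometric(0.5) extra copies with probability
`duplication_rate`), terminal deamination (C→T from the 5′ terminus at
`damage_rate`, halving per base inward, mirrored G→A at 3′) applied to the
molecule and therefore shared by both mates, and per-read substitution
errors applied to the fragment-derived bases before the adapter is
appended. Reads shorter than the fragment simply cover its ends; fragments
shorter than the read length read through into the adapter and then into
random bases. Baseline qualities are drawn at 38–41; erroneous bases
receive a telltale low quality (≤ 15) with probability 0.5 so that
quality-aware logic sees both detectable and undetectable errors.

Every output draws from an RNG stream keyed by (seed, stream name), making
runs byte-reproducible and outputs mutually independent. Truth tables tie
each read to its origin, duplicate group and planted variants; truth SAMs
place each merged fragment at its true coordinates (elongated mode emits
origin-spanning fragments as single records in the elongation window,
linear mode drops them, modelling a linear mapper's failure), and all-sites
VCFs draw Poisson depths (default mean 20) with occasional single stray
alt reads (p = 0.002) to exercise the single-minor-read rule.

Not emulated: indels, machine-specific error/quality profiles, library
complexity saturation, mapping ambiguity and alignment errors (truth SAMs
are perfect placements). Passing tests therefore demonstrate the
correctness of the stage logic under controlled conditions, not robustness
to mapper artefacts on real data.

## Study sizes and test design

The test suite and the acceptance script run at desk scale, chosen so the
statistical checks have clear margins: merge round-trips on 1 000 pairs of
20–80 bp fragments at read length 100 (the length filter is set to 20
there, matching the smallest simulated fragment), the error grid at 300
pairs per rate, adapter residue over 10⁴ reads, circular evenness with
2 000 fixed 60 bp fragments on a 5 kb genome (per-base coverage within
4 binomial SD of the mean across the origin), dedup oracle equivalence on
≤ 2 000 records at 30 % duplication, and draft recovery of 50 SNPs at depth
20. The linear-mapping end dip is reported as the median over three
simulation seeds because the per-base dip at the boundary is a single
Poisson(0.4) draw whose run-to-run noise would otherwise dominate the
statistic. Brute-force oracles (full alignment enumeration, exhaustive
overlap search, all-pairs duplicate grouping, an independent transcription
of the call cascade) back the main paths in the tests.

## Known limitations

* Dovetail read pairs (R̄ extending past F's 5′ start) are not merged.
* Exactly one circular sequence per run; multi-target circularity is out
  of scope.
* BAM/CRAM are not read or written; SAM text is the contract surface.
* Drafts are haploid consensus calls; heterozygotes are not represented.
* Positive-insert paired-end duplicate marking is out of scope (merged and
  single-end reads are the target data).
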