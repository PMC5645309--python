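# Methods

This note documents the models implemented in `fourcmap`, the assumptions
behind them, every user-facing parameter with its default and rationale,
what the synthetic generator emulates, the numerical conventions, and the
known limitations.

## 1. Experimental model

A 4C-seq library is read as follows. The genome is digested in silico
with a primary restriction enzyme (default DpnII, motif `GATC`); the
resulting *primary fragments* are the unit of quantification. Each
sequenced pair carries, on one mate, the bait-specific forward primer
ending in the primary motif, followed by the sequence of the captured
fragment; the other mate carries the reverse primer (from the secondary
digest side of the bait). Analysis stages:

1. **Demultiplexing** — a pair is assigned to a bait when one mate starts
   exactly with the forward primer and the other with the reverse primer
   (either mate order). Primers must be unique and non-nested across
   baits.
2. **Trimming** — the forward mate is trimmed to start at the primary
   motif (the last `len(motif)` bases of the primer are kept, so the
   captured sequence begins with the restriction site, as it does in the
   genome). Low-quality 3′ suffixes (Phred < 20) are removed; reads
   shorter than 30 bp are dropped.
3. **Alignment** — unique exact match over both strands. The fragment
   credited with the read is the one containing the 5′-most aligned base
   (leftmost genomic coordinate for a `+` alignment, rightmost for `−`).
   Non-unique and unmatched reads are tallied as unmapped.
4. **Filtering** — three standard 4C artefact filters, applied by zeroing
   fragments: *self-ligated* (the bait fragment itself), *uncut* (the two
   fragments index-adjacent to the bait), and the *control blacklist*
   (every fragment with ≥ 1 read in a non-ligated control library, which
   marks material that survives without a ligation junction). The filter
   report records reads removed per rule; removed + retained equals the
   assigned total.
5. **Profiles** — reads-per-million normalisation (denominator = retained
   reads after filtering, so profiles are comparable across replicates
   with different artefact loads), a centred running window over
   `smoothing_window = 9` fragments (edge-truncated), and a cumulative
   read fraction versus distance from the bait.
6. **Interaction calling and annotation** — described in the README and
   in §2 below.

**Mappability.** A fragment is flagged mappable when the `read_len`-mer at
its start occurs exactly once in the genome across both strands. This is
a deliberate surrogate for an external mappability track: it uses exactly
the criterion the exact-match aligner applies to the reads that matter
(trimmed captured reads begin at fragment starts). A palindromic start
k-mer counts its own reverse complement and is therefore unmappable,
consistent with the aligner's both-strand uniqueness rule.

## 2. Interaction caller

Counts on the mappable fragments of a region (bait fragment and its two
neighbours excluded) are summed over sliding windows of `window = 3`
fragments. The null shuffles the per-fragment count multiset uniformly
over the fragment positions; `iterations = 1000` permutations are drawn.
Candidate thresholds are the distinct observed window sums at or above the
`m`-th largest, with `m = max(1, floor(fdr_prob · n_windows))` and
`fdr_prob = 0.05` — i.e. the top-5 % tail of observed windows, made
concrete as a rank rule so ties are handled deterministically. For each
candidate `T`, the FDR estimate is the mean permuted exceedance count
divided by the observed exceedance count; the calling threshold is the
smallest candidate with estimate `< fdr = 0.01`. When no candidate
qualifies (e.g. permutation-invariant flat counts), the region has no
significant interactions.

Significant windows whose fragment ranges overlap or touch are merged.
Robustness categories re-test each merged interval after perturbing its
highest-count member fragment (lowest index on ties): zeroed → category 1;
replaced by the mean of its flanking fragments (in mappable-index space) →
category 2; otherwise category 3. Replicate reproducibility discards
category 3, requires ≥ 1 bp overlap between a rep1 and a rep2 interval,
reports the intersection span, and colours the result red only when both
parents are category 1.

Parameter rationale: `window = 3` is the smallest odd window that cannot
be produced by a single fragment plus the category rules; `fdr = 0.01`
and `fdr_prob = 0.05` restrict calls to the strongest tail while the
1000-iteration null keeps the FDR estimate's resolution at 10⁻³ relative
to a single observed window.

## 3. Annotation

Transcription-factor co-binding clusters are maximal runs where ≥
`min_tfs = 6` *distinct* TFs cover a position (per-TF peaks merged first
so one TF never stacks with itself; computed by a sweep line), extended to
the union span of contributing peaks. Six TFs overlapping only pairwise
in a chain never reach multiplicity six and yield no cluster. A cluster
with a reproducible interaction at or within `max_dist = 2000` bp
(span-to-span gap, 0 on overlap) becomes an enhancer candidate. Candidate
names are the cluster midpoint's distance from the bait gene's TSS,
signed in the direction of transcription and rounded to the nearest kb.
Promoter overlap uses a 2000 bp window 5′ of the TSS on the gene's
strand. The cohesin flag is true iff a Rad21 peak overlaps the cluster
span with no CTCF peak there.

## 4. What the generator emulates

`make_toy_genome` builds a deterministic toy genome: restriction sites are
planted on 4-bp slots with probability `4 · site_density`
(`site_density = 1/250`, so the mean primary fragment is ~250 bp, typical
of a 4-cutter), giving a Binomial site count. Chromosome 1 carries a
contact domain over its central 2/5, a bait near the domain centre, and
five planted enhancer loci inside the domain; a second chromosome
provides trans background, and a 150 bp duplicated block creates
unmappable fragments so the mappability path is exercised. Annotation
tracks emulate the regulatory context: a 6-TF co-binding cluster, a Rad21
peak and no CTCF at each planted locus; Rad21+CTCF at the domain
boundaries; conserved non-coding elements on two planted loci; one 5-TF
decoy cluster 800 bp from a planted locus (below the co-binding
threshold) and one 6-TF decoy far outside the domain, > 2 kb from any
interaction (testing the distance rule).

`simulate_4c_library` draws each read pair from a multinomial over three
read classes — self-ligated (`p_self = 0.2`), uncut (`p_uncut = 0.05`),
captured — matching the large bait-proximal artefact load of real
libraries. Captured fragments follow the contact model

&nbsp;&nbsp;&nbsp;&nbsp;`w_j ∝ (ε + γ_j) · β^cross(j) · (1 + |mid_j − mid_bait| / s)^(−α)`

in cis, with background floor `ε = 0.02`, distance scale `s = 50 000` bp,
decay exponent `α = 1` (the shallow power-law decay of intra-domain
contacts), attenuation `β = 0.3` per domain-boundary crossing, a flat
trans weight of 0.005, and planted enrichment `γ_j = 20` on each planted
fragment. Planted loci are *runs of three consecutive fragments*: under
a multiset-shuffle null a single enriched fragment follows itself into
every permutation and is inseparable from its own null, whereas a run of
three is detectable exactly through the 3-fragment window — the planted
signal therefore tests the caller's actual discriminative mechanism.
Reads are 75 bp; the forward mate is primer + fragment sequence, mate
order is randomised, and qualities are constant. The non-ligated control
(`control_reads = 5000`) lands uniformly on a sparse 1 % fragment subset
chosen away from the planted loci and their neighbours, so blacklisting
removes genuine artefact positions without erasing ground truth.

Standard scenario size: two chromosomes, `chrom_len = 500 000` bp
(~2000 fragments on chr1 — large enough for a stable permutation null,
small enough to simulate and analyse in seconds), `n_reads = 200 000` per
replicate. These sizes are package choices made for tractable,
fully-in-memory runs; all of them are configurable.

## 5. Numerical conventions

- Coordinates are 0-based, half-open throughout; fragment indices are
  per-chromosome and aligned across all arrays.
- All randomness flows from `numpy.random.default_rng` seeds. Library
  seeds derive from the scenario seed as `base·4 + {1,2,3}` with
  `base = seed mod 2²⁸`; each (bait, region) calling seed is
  `(seed · 1 000 003 + crc32("bait:region")) mod 2³¹`. Every derived seed
  is below 2³¹.
- Window sums use cumulative-sum differences; counts are integers, so the
  float cumsums are exact (well below 2⁵³) and the caller is bit-for-bit
  reproducible against a pure-Python reference given the same permutation
  stream (one `rng.permutation` of the count vector per iteration).
- Permuted exceedance totals are accumulated as 64-bit integers; the FDR
  estimate divides by the iteration count first and the observed count
  second, fixing the floating-point evaluation order.
- On-disk runs write a manifest of sha256 checksums; a rerun with an
  up-to-date manifest is skipped unless forced, and forced reruns are
  byte-identical.

## 6. Limitations

- The aligner is exact-match only: no mismatches, indels or quality-aware
  placement. It is adequate for the generator's error-free reads and for
  small genomes, not a replacement for a production aligner on real data.
- The mappability surrogate considers only the fragment-start k-mer on
  the digested genome, not blind spots elsewhere in a fragment.
- The permutation null assumes exchangeable fragment counts within a
  region; it does not model the smooth distance decay, which is why
  calling is restricted to the top observed tail rather than genome-wide.
- The multiset-shuffle null cannot, even in principle, flag a single
  enriched fragment (see §4); single-fragment signals surface only as
  category-3 calls, which the reproducibility step discards. Relatedly,
  an interaction whose member fragments carry near-equal counts just
  above threshold can fall to category 3 in one replicate and drop out.
- The generator draws reads from a fixed multinomial: no PCR duplicates,
  ligation chimeras, sequencing errors or coverage biases beyond the
  contact model.
- Replicate intersection is pairwise (two replicates); candidate calling
  considers distance to clusters only, not orientation or signal shape.
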