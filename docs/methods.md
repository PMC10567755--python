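# Methods

`splicemotifs` asks whether the binding motifs of RNA-binding proteins
(RBPs) are over- or under-represented around the splice sites of a set of
*regulated* cassette exons, relative to a large random background of
internal exons, and supplies the supporting statistics: PSI/ΔPSI
quantification of skipped-exon (SE) events, differential-splicing
filtering, RNA-map positional profiles, and per-splice-site splicing
efficiency. Everything is verifiable offline through a deterministic
synthetic-data generator with an explicit truth record.

## Splicing quantification

PSI for one sample is the length-normalised junction-read ratio

    PSI = (I / L_I) / (I / L_I + S / L_S)

with I inclusion-junction and S skip-junction counts and L_I, L_S the
effective lengths of the two isoform forms (the rMATS convention; with
L_I = L_S this reduces to I/(I+S)). PSI is undefined (NaN, never 0) when
I + S = 0. ΔPSI is the difference of group-mean PSI, group 2 minus
group 1, i.e. treatment minus control. The differential (DAS) filter
keeps events with |ΔPSI| > 0.1 and adjusted p < 0.05, both strict
inequalities; events lacking an adjusted p are excluded with a warning
rather than silently kept.

The event tables read and written are the de-facto tab-delimited SE
dialect (`exonStart_0base`/`exonEnd`, comma-separated `IJC_SAMPLE_*`
lists, `IncFormLen`/`SkipFormLen`, `PValue`, `FDR`,
`IncLevelDifference`). The adjusted p column is taken as-is when an
external caller produced it; for synthetic data an internal test is used:
a two-sided Fisher exact test on the pooled per-group inclusion/skip 2×2
table with Benjamini–Hochberg adjustment across events. This internal
test is a deliberately simple stand-in for a dedicated DAS caller and is
intended for simulated counts only.

## Regions around splice sites

For each SE event, four windows are cut in transcript order: `5ss1`
(donor of the upstream flanking exon), `3ss1` (acceptor of the cassette),
`5ss2` (donor of the cassette) and `3ss2` (acceptor of the downstream
flanking exon). Each window spans the splice site with `e` exonic and `i`
intronic nucleotides (defaults e = i = 100). Background internal exons
contribute one donor (`5ss`) and one acceptor (`3ss`) window each, with
the same parameters. Sequences are always reported 5'→3' on the RNA sense
strand, so a donor window reads exon-then-intron and an acceptor window
intron-then-exon regardless of genomic strand; region extraction is
exactly invariant under reverse-complementing the genome and flipping all
strands (a tested bitwise identity).

Two numerical edge policies: an exon shorter than `e` truncates the
exonic extent (region flagged); a window running past a contig end is
clipped with a warning and dropped entirely if less than half the
configured window survives. Windows with e = i = 0 are rejected. Both
extents are exposed so an exon-side-only reading (i = 0) is one flag
away.

## Background exon sampling

The background is a uniform, seed-reproducible sample without replacement
from internal exons (both splice sites defined) of length ≥ 8 nt,
default n = 150,000 at genome scale. Restricting to internal exons
matches the cassette-exon unit being contrasted; requesting more exons
than the eligible pool is an explicit error naming the pool size.

## Motif scanning

Motifs are IUPAC RNA consensus strings from an ATtRACT-style catalog
(U ≡ T on read, organism-filtered, unique matrix ids). Scanning is exact
degenerate matching with no mismatches, on the sense strand only — RBPs
bind RNA, so the antisense strand carries no signal — and every
overlapping occurrence counts. An N in the scanned sequence matches no
consensus position; N in a consensus matches any base. These choices are
recorded in every output's metadata header. PWM scanning is out of scope:
the catalog's consensus strings are the unit of analysis.

Two scan implementations exist with identical semantics: a per-sequence
compiled-regex scan with a lookahead (so overlaps are counted) and a
vectorised numpy lookup-table scan used by the enrichment stage for bulk
counting; tests pin both to an explicit per-position loop oracle.

## Enrichment statistics

For each motif × region label, the contingency table is built under a
per-position opportunity model:

    a = occurrences in regulated regions of the label
    b = scanned start positions in those regions − a
    c = occurrences in matched background regions
    d = scanned positions in background − c

with scanned positions = Σ max(len − m + 1, 0). Donor-side labels
(`5ss1`, `5ss2`) are contrasted against background `5ss` regions,
acceptor-side against `3ss` — like-for-like splice-site context. The
opportunity model is robust to unequal region counts and lengths; a
per-region presence/absence model is available behind
`table_model="presence"` and recorded in metadata.

Enrichment is the right-sided exact Fisher test P(X ≥ a) and depletion
the left-sided P(X ≤ a), X hypergeometric on the table margins.
P-values are BH-adjusted across motifs within each (region label, side)
family — each label is tested separately because calls are reported per
individual region. A motif is called `enriched` (or `depleted`) when the
corresponding adjusted p < α (default 0.05), `ns` otherwise; with
one-sided tails summing to more than 1, both calls can never fire at
α ≤ 0.5. Odds ratios (ad/bc) are reported, missing when bc = 0; calls
rely on p-values only. Exact tail probabilities are floored at the
smallest positive float to guard against underflow on extreme tables.

One property worth stating plainly: the BH step-up map is *not*
idempotent — re-adjusting an already-adjusted vector can only raise
values (e.g. [0.01, 0.5] → [0.02, 0.5] → [0.04, 0.5]), a known feature
of the standard step-up construction shared by statsmodels and R's
`p.adjust`. The tests document this actual behaviour.

RNA maps (positional profiles) report, per offset relative to the splice
site (negative = 5' of the site on the RNA), the fraction of regions with
a motif occurrence starting at that offset; only full-window regions
enter a profile so every offset is defined for every region.

## Splicing efficiency

At every annotated exon–intron boundary, a read is *spliced* support when
its alignment gap (CIGAR N) equals an annotated intron exactly — such a
read supports both boundaries of that intron — and *unspliced* support
when one contiguous aligned block covers [pos − k, pos + k), k = 6 nt
overhang by default. Efficiency is θ = spliced / (spliced + unspliced),
with sites under 10 informative reads excluded. Multi-gap reads
contribute each gap independently; deletions break block contiguity
(conservative). Groups are compared per site kind (5'ss, 3'ss) with a
paired Wilcoxon signed-rank test on matched sites; fewer than 10 matched
sites yields a summary without a test. The efficiency definition, read
filters and test are this package's own operationalisation and are named
in output metadata.

## Synthetic data

The generator builds a single-contig genome of i.i.d. bases at a chosen
GC with regularly spaced multi-exon genes (random strand), picks one
cassette per selected gene with its transcript neighbours as flanks, and
samples background internal exons disjoint from all event exons.

*Motif planting* writes concrete realisations of one consensus in-place
(bases replaced, coordinates preserved) at Poisson-distributed,
non-overlapping sense-strand offsets: `background_rate` expected starts
per 100 nt everywhere, `background_rate × multiplier` in the regulated
regions of one target label. Defaults are 1,000 regulated events, 10,000
background exons, a 20-motif catalog, background rate 0.2/100 nt and
multiplier 5 (0.2 for depletion studies). The rate was chosen so that
even at the 5× multiplier under 2% of region bases are rewritten:
in-place replacement at unequal volume between regulated and background
regions would otherwise measurably dilute the occurrences of the *other*
19 motifs and corrupt their null. For the same reason the demo catalog —
real RBP names, synthetic hexamer consensus strings — is constructed so
no non-planted motif matches the planted RBFOX2 UGCAUG hexamer or shares
a ≥3-nt end-overlap with it (both asserted by tests). Exon length 250 nt
and intron length 300 nt keep the default 100+100 windows of neighbouring
splice sites disjoint, so planting in one region never bleeds into
another.

*Junction counts* are beta-binomial per replicate (ICC parameterisation;
ρ = 0 recovers the binomial; default ρ = 0.01, which inflates the
binomial SD ≈1.4× at coverage 100 — a typical replicate-level
overdispersion). Effective lengths are written equal so PSI estimation
inverts the count model exactly. Default design: 3 vs 3 replicates at
coverage 100.

*Efficiency reads* place each simulated splice site on its own two-exon
transcript; spliced (gapped) and contiguous reads mix at the site's true
θ, Binomial(depth, θ) at depth 200 by default. The companion boundary of
each intron accumulates spliced counts as a side effect and is
deliberately not a truth site, so per-site θ recovery is uncontaminated.

What the generator does *not* emulate: sequencing errors, mappability and
alignment artefacts, non-uniform coverage, realistic exon/intron length
and composition distributions, paired reads, or correlated motif
co-occurrence. Passing recovery tests therefore demonstrate correctness
of the statistics and bookkeeping under the stated model, not robustness
to real-data artefacts.

## Problem sizes in the test suite

Recovery tests run at the default study scale (1,000 events / 10,000
background exons / 20 motifs) over 20 seeds for the planted-motif
criteria, 20 seeds of 90-event PSI grids and 100-event power sets, and 20
seeds of 500-site efficiency comparisons at depth 200; the Fisher oracle
is enumerated exhaustively for all 2×2 tables with N ≤ 40. The
acceptance script reports the same quantities at 10 recovery seeds
(5 for efficiency) and N ≤ 30 for the Fisher enumeration — sizes chosen
to keep a full from-scratch rerun in the minutes range while leaving the
statistical conclusions unchanged.

## Known limitations

- The internal DAS test ignores replicate structure beyond pooling and
  carries no isoform-length likelihood model; real studies should feed an
  external caller's table.
- Exact gap-to-intron matching tolerates no alignment wobble; soft
  junction tolerance is deliberately excluded for determinism.
- Event matching across contrasts is by exact cassette coordinates; no
  fuzzy matching.
- Only SE events get region extraction; A5SS/A3SS/MXE/RI events are
  counted in proportions but not scanned.
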