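# Methods

## Scope and model

`redigest` predicts how a panel of restriction endonucleases fragments a
genome, from sequence alone. The model is purely sequence-based: an enzyme
is its IUPAC recognition motif, every exact motif occurrence is a potential
cut, and fragments are the intervals between consecutive occurrences. Real
chromatin digestion additionally depends on nucleosome occupancy, enzyme
kinetics and buffer conditions; none of that is modelled, which is precisely
why the in silico prediction is useful as a *design bound* — regions the
model already calls refractory cannot be rescued by longer incubation.

## Conventions and definitions

* **Coordinates** are 0-based half-open (BED) everywhere. A site coordinate
  is the *start* of the recognition-site occurrence. The chemical cut
  position within the site (`cut_offset`, e.g. AG^CT for AluI) is carried in
  the registry as metadata from standard enzymology but is not used for
  fragmentation: fragment boundaries at site starts shift every boundary by
  at most a motif length and leave every headline statistic (counts,
  fractions, densities) unchanged, while keeping a single convention for
  mixed panels.
* **Scanning** reports overlapping occurrences (sliding-window semantics)
  with no suppression rule. Soft-masked lowercase bases are ordinary bases;
  hard-masked `N` blocks any window overlapping it, so assembly gaps
  naturally surface as long undigested fragments. Non-nucleotide characters
  are an error with a coordinate, not a silent skip.
* **Strands.** For palindromic motifs (all five registry enzymes: AluI
  `AGCT`, SaqAI `TTAA`, HinfI `GANTC`, MvaI `CCWGG`, BsuRI `GGCC`) scanning
  one strand or both is provably identical, so the default `both_strands`
  mode costs nothing; for non-palindromic motifs it additionally scans the
  reverse-complement pattern and labels those hits `-`.
* **Fragmentation.** Site coordinates are deduplicated across enzymes and a
  site at coordinate 0 is dropped, so zero-length fragments cannot occur and
  fragment lengths always sum to the chromosome length. This conservation
  invariant is asserted on every access.
* **Thresholds are strict.** "Below threshold" means `length < t` and
  "refractory" means `length > t`; fragments of exactly `t` bp fall in
  neither and are counted separately in the report
  (`n_fragments_exactly_threshold`), so the two headline statistics plus the
  boundary class always partition the genome.
* **Denominators.** The genome fraction below threshold is reported both
  over the full assembly length (N runs included) and over non-gap sequence
  (assembly minus N bases). The two bracket any reasonable definition; on
  gap-poor genomes they coincide.
* **Refractory regions are whole fragments**, not clipped sub-intervals:
  the question they answer is "which stretches does the digest fail to
  break", and that is a property of the fragment.

## Annotation and per-class metrics

* Refractory-region classification uses **any-overlap (≥ 1 bp)** membership
  against each track (gap, blacklist, repeat, ...). Labels are not mutually
  exclusive — one region may be both gap- and repeat-overlapping — so
  per-track counts may sum to more than the number of labelled regions; the
  regions carrying no label are the "unique" poorly fragmentable genome.
* **Sites** are assigned to a class interval by their start coordinate;
  **fragments and sequenced templates** by their midpoint. Midpoint
  assignment is single-valued and total when the classes partition the
  genome (per-class counts sum to the total), at the cost of ignoring
  partial overlap of long fragments — an explicit, documented choice; the
  headline per-state inequalities are robust to it. A class interval that
  contains no fragment midpoint is scored by the fragment(s) enclosing its
  interval midpoints (the enclosing-fragment convention), so no class is
  ever unreported.
* Overlapping intervals within one track are merged before length and
  density computations, making densities invariant to how the track was
  assembled. Class exclusions (e.g. repeat-associated chromHMM states 14 and
  15 in a K562 15-state segmentation) are a configurable label list.
* Chromosome-name normalisation (`chr1` vs `1`) is an explicit flag, never
  silent.
* BEDPE records are collapsed to the outermost coordinates of the pair
  (the sequenced template); inter-chromosomal or otherwise malformed records
  are skipped and counted, and more than 10% malformed is a hard error.

## Analytic spacing

For composition `p` summing to 1 (validated to 1e-9), the per-position
density of a panel is the sum over enzymes and over the Cartesian expansion
of each motif of the product of per-base probabilities, with
reverse-complement expansions added for non-palindromic motifs in
both-strand mode. Expected spacing is the reciprocal; edge effects and
self-overlap corrections are ignored, which is exact in the mean-density
sense (the observed mean spacing of simulated sequences matches within
Monte-Carlo error; the spacing *distribution* is only asymptotically
geometric because motif occurrences are not independent at overlapping
offsets). A panel impossible under the composition (zero density) is an
error rather than an infinite spacing.

## Synthetic data generator

The simulator emulates what the real inputs look like to this toolkit:
i.i.d. background sequence of configurable base composition (default
uniform), N-run gaps, recognition motifs planted at known coordinates, and
per-class paired-end template files with known length distributions
(log-normal by default, the usual shape of size-selected libraries, with
median as the natural location parameter). Planted motifs are overwritten
*after* background generation, so chance background occurrences of the same
motifs remain present and scanners are tested against the full truth
(planted ∪ chance), not a sanitised one. One integer seed drives a single
`numpy.random.default_rng` stream per fixture, making every output
byte-reproducible.

What the simulator deliberately does not emulate: base-composition
heterogeneity along chromosomes (isochores, CpG islands), repeat structure,
and chromatin-state-dependent cutting efficiency. Tests passing on these
fixtures therefore validate the *computational* claims (scanning,
interval arithmetic, statistics) — not the biological fidelity of any
prediction for a real genome.

## Problem sizes

Unit and property tests run on sequences up to 2 kb (1,000-sequence oracle
comparison) and simulations of 0.2–2 Mb; the acceptance script simulates
10 Mb, which puts the Monte-Carlo standard error of the mean spacing near
1.3 bp — small enough to resolve the 256-bp analytic value, large enough to
run in seconds. Genome-scale runs (e.g. hg19 with the four-enzyme panel,
>50 M sites) stream one chromosome at a time, so memory is bounded by the
largest chromosome plus its site arrays.

## Known limitations

* No modelling of methylation sensitivity, star activity or partial
  digestion; predicted cutting is all-or-nothing at exact motif matches.
* `cut_offset` mode shifts boundaries but still assumes both strands cut at
  one coordinate (blunt-cut abstraction).
* GFF-style 1-based inputs are out of scope; all interval inputs are BED.
* Per-class observed-length metrics trust the template intervals as given;
  no duplicate-read or mapping-quality filtering is applied.
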