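# Methods

## The measurement model

eeTAPS reads DNA methylation from *where fragments end*. After TAPS
conversion (5mC/5hmC → DHU; the two marks are not distinguished — the
methylome level is total TAPS-convertible modification), USER digestion
cleaves the double strand at converted CpG dyads. For CpG site `i`, each
sequenced fragment either terminates at `i` (cleavage evidence, count `c`)
or spans the dyad without terminating (read-through evidence, count `r`),
and the called level is the cleavage fraction `c / (c + r)`. Sites with
`c + r = 0` are *uncovered*, which is distinct from level 0. A site is
designated mCpG when `level > 0.1` (strict) and `c >= 1`; coverage
criteria default to depth ≥ 1 for this enrichment assay and depth ≥ 5 for
quantitative (whole-genome / reduced-representation) comparators.

### Fragment reconstruction and endpoint attribution

Only properly paired alignments whose read 1 carries flag 83 or 99 are
used; the fragment is the template span of the pair. A cleavage at site
`i` excises the 2 bp dyad (the `dyad_gap` convention, configurable): the
upstream fragment ends at `i` (exclusive) and the downstream fragment
starts at `i + 2`. Inverting this, a fragment's left endpoint `s`
attributes to the CpG with its C at `s - dyad_gap` and the right endpoint
`e` to the CpG at `e`. When no CpG sits exactly at the canonical position,
the nearest CpG within `offset_window` bp (default ±2, ties to the smaller
coordinate) is used to absorb end-repair ambiguity; an endpoint matching
no CpG is treated as a shear/molecule end and contributes no cleavage
evidence anywhere. Each fragment contributes at most one cleaved count per
site (its two endpoints are deduplicated), and every CpG dyad fully
interior to the span that was not endpoint-attributed contributes one
read-through count. Counts are additive, so tallies are invariant to
fragment order and batching.

### Estimator properties: what the cleavage fraction estimates

Let θ = m · conversion · cleavage be the per-molecule probability that
site `i` on a covering molecule is cut. Two sampling regimes matter:

* **One informative fragment per molecule** (e.g. the site sits at a
  molecule boundary, or only one flank is recovered): the cleavage
  fraction is an unbiased Bernoulli estimate of θ, and m̂ = level /
  (conversion · cleavage) recovers the truth. The parameter-recovery tests
  use this end-anchored design.
* **Both flanking fragments recovered** (interior sites of long molecules,
  full fragment recovery): a cut produces *two* fragment ends at the site
  while an uncut molecule produces one read-through, so the expected level
  is 2θ/(1+θ) > θ. This is an inherent property of endpoint counting, not
  an implementation artifact; it is one reason the assay is
  semi-quantitative at single-CpG resolution, and it is asserted as such
  in the test suite (`test_molecule_level_double_count_bias`).

The level remains 0 at θ = 0 and 1 at θ = 1 in both regimes, so binary
methylomes round-trip exactly, and the level is monotone in m, so ranking
and thresholding (mCpG designation) are well behaved. Size selection adds
a second, density-dependent distortion (fragments from very dense or very
sparse regions fall outside the retained 100 bp–1 kb window), which
`density_bias` characterises empirically per truth-density bin rather than
correcting.

## The simulator

The simulator defines the conditions under which the caller is validated.

* **Genome**: first-order Markov chain over {A,C,G,T}. `gc_fraction`
  (default 0.5) sets the stationary composition; `cpg_depletion` is the
  target observed/expected CpG dinucleotide ratio (mammalian genomes
  ~0.2–0.25). The internal C→G transition weight is solved numerically so
  the *stationary* O/E ratio equals the parameter — naive down-weighting
  would miss, because renormalisation shifts the stationary base
  frequencies. Depletion 0 emits no CG at all. No repeat structure or
  per-region composition is modelled; CGI-likeness comes from the
  methylome, not the sequence.
* **Methylome**: per-CpG levels drawn from Beta(8, 2) (mean 0.8, the
  high-methylation background typical of mESC gDNA) outside regions and
  Beta(1, 9) (mean 0.1, CGI-like depletion) inside; a float pins a point
  mass. Methylation is symmetric across the dyad — hemimethylation is not
  modelled, so one Bernoulli per site per molecule governs conversion.
* **Chemistry**: conversion_rate defaults to 1.0 and false_conversion_rate
  to 0.0 (both configurable; the TAPS error rates are small and not the
  object of study here). Cleavage of a converted dyad is context-dependent
  on the base preceding the C: ACG 0.924, TCG 0.826, CCG/GCG 0.85
  (CCG/GCG default to the overall USER efficiency of 0.85 and are
  configurable); a context-free mode uses 0.85 throughout. Cleavage is a
  single per-site double-strand Bernoulli — per-strand nicking is not
  identifiable from overall efficiencies and is not modelled.
* **Digestion**: a cut at site `i` splits `[a,b)` into `[a,i)` and
  `[i+dyad_gap,b)`; empty pieces (adjacent cuts 2 bp apart) are dropped.
  Exact length conservation (Σ fragment lengths + 2·cuts = molecule
  length) holds for dyad_gap ≤ 2; whether the real end-repair leaves a 1
  or 2 nt gap is a convention shared with the caller, not a measured fact.
  A CpG flanked at 2 bp on both sides by other cut CpGs loses both
  adjacent pieces to excision and leaves no boundary.
* **Library**: size selection retains 100 bp–1 kb inclusive. Reads are
  paired-end 80 bp, read 1 from either strand with equal probability
  (flags 99/83), uniform substitution errors only (no indels or quality
  model), constant Q40. Truth alignments are emitted as valid SAM so the
  caller's extraction path is exercised without an aligner.
* **Molecules**: uniform positions, normal lengths truncated at contig
  bounds; `whole_contig_molecules` models the un-fragmented-gDNA premise
  and is used where shear ends must not fall near CpGs.

What passing tests therefore do **not** show: robustness to alignment
error, PCR duplicates and amplification bias, indels, hemimethylation,
non-CpG methylation, or realistic repeat content. The simulator's truth
SAM bypasses trimming/alignment by design.

## Downstream analytics

Window (default 100 kb) and region means are *unweighted* arithmetic means
of levels over covered sites (depth weighting is available behind a flag);
empty windows/regions carry NaN, never 0, and are dropped from
correlations. Metaprofiles scale each region to a fixed bin count with
fixed-width flank bins (default 4 kb flanks); regions are unstranded. The
moving average is a centred window of half-width `bw` (2·bw+1 points),
truncated at the ends, NaN-excluding. Down-sampling draws one uniform per
fragment and thresholds at the fraction, so retained sets are nested
across fractions for a fixed seed and depth-saturation curves are
internally monotone. The in-silico MspI digest cuts every C^CGG on the
plus strand, retains 100–400 bp pieces, and counts CpG dyads inside
retained pieces as coverable — a coverage-set comparison only; no attempt
is made to simulate a base-conversion caller for the reduced
representation arm. Fragment-end QC classifies each end by the reference
base at its canonical attribution position and by signed distance to the
nearest CpG (distance 0 = on-CpG cleavage).

## Numerical and design choices

* Coordinates are 0-based half-open everywhere; a site is the plus-strand
  C position; BED/bedGraph outputs follow BED semantics.
* Endpoint-attribution ties (equidistant CpGs) resolve to the smaller
  coordinate; duplicates are not collapsed; discordant/unpaired reads are
  dropped; zero/negative template spans are skipped with a warning.
* Pearson correlation requires ≥ 2 shared finite observations and nonzero
  variance on both sides, else NaN.
* Truth mCpG in simulations is defined as truth level > 0.1, the same
  threshold family as the calling criterion, so recall/precision compare
  like with like.
* Problem sizes in tests and in `scripts/acceptance.py` (10 kb–1 Mb
  genomes, 10²–10⁴ molecules, 10⁴ Bernoulli trials per recovered
  probability) are chosen so every stochastic assertion has ≥ 3-SE
  headroom while a full run stays in the seconds-to-minutes range on one
  core.

## Known limitations

* Single-CpG levels are semi-quantitative (double-count bias above);
  consumers should prefer window/region summaries for quantitative use.
* CCG/GCG cleavage efficiencies are placeholders at the overall USER rate.
* The density-dependent size-selection bias is characterised, not
  corrected.
* The simulator emits perfect truth alignments; mapping ambiguity in
  repetitive sequence is out of scope.
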