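# Methods

## Scope and model

`codonshift` infers the genetic code operating in an organellar genome from
three complementary signals: the amino acids conserved at the alignment
columns where each codon occurs, the positional distribution of candidate
termination codons (internal vs terminal), and the identity elements of the
tRNAs that would have to decode a reassigned codon. RNA editing is handled
upstream, because codon meaning is a property of mature transcripts rather
than of the genome sequence.

The inference makes no explicit evolutionary model assumptions beyond what
the conserved-column statistic implies: reference orthologs must be similar
enough that homologous columns are meaningful, and diverse enough that a
70 % consensus is informative. It is a counting procedure, not a
likelihood method; its strength is transparency (every call carries its
evidence counts), its weakness is low sensitivity for rare codons — a codon
below the evidence floor keeps its standard meaning and is reported as
`insufficient-evidence`, never silently decided.

## Decision thresholds

Per codon, with `N(a)` the number of conserved columns of consensus `a`
carrying that codon:

| parameter | default | meaning |
|---|---|---|
| `conservation_threshold` | 0.70 (inclusive ≥) | column consensus frequency |
| `min_conserved` | 5 | evidence floor, `ΣN(a)` |
| `max_standard_fraction` | 0.10 (strict <) | tolerated standard-meaning fraction |
| `min_top_count` | 5 | support needed for an alternative meaning |
| `dominance_ratio` | 2.0 (inclusive ≥) | top vs runner-up margin |

Boundary conventions: the conservation and dominance comparisons are
inclusive; the standard-fraction test is strict (a codon with exactly 10 %
standard placements is called standard). A codon passing the reassignment
trigger but failing dominance or support is translated as `X`. Exact ties
between amino-acid counts are broken alphabetically, making calls
deterministic. All five thresholds are `DecisionParams` fields and CLI
options; an `inclusive=False` switch gives the strict (> 0.70) reading of
the conservation threshold.

The focal row is excluded from the conservation denominator by default so a
mistranslated focal residue cannot vote for its own conservation; gaps
count in the denominator (`gap_policy="count-in-denominator"`), and columns
with fewer than 4 non-gap reference residues are never called conserved.
Both choices are flags.

Two iterations are run because the first pass may free codons from wrong
standard meanings: the genome is retranslated under the first-round calls
and re-profiled against a narrower panel of close relatives, whose columns
are conserved at positions a broad panel blurs. Both call sets are
retained in the outputs.

## Stop scan and wobble rules

A sense-to-stop reassignment produces a codon that is used, but exclusively
as the annotated terminal codon, and that lacks a decoding tRNA. Verdicts:
`sense` (any internal use), `absent` (unused), `stop-candidate`
(terminal-only, undecodable), `ambiguous` (terminal-only but decodable).
Decodability defaults to classical wobble (G34 reads C and U; U34 reads A
and G); superwobble (U34 reading the whole four-codon box) is opt-in
because it requires an unmodified U34, which sequence data cannot
establish. The final inferred table applies second-iteration sense calls
first, then stop candidates.

## tRNA structural frame

Rather than a covariance-model alignment, tRNAs are parsed from two robust
landmarks: the acceptor stem (first seven bases paired with the seven bases
preceding the discriminator, allowing G·U) and the anticodon loop, located
by scanning for a 5-bp stem enclosing a 7-nt loop. Candidate loops are
ranked by the classical conserved loop bases (C32, U33, purine-37), then by
centrality, then 5'-ward. A 3'-terminal `CCA` is ambiguous — it may be the
post-transcriptionally added end or simply stem bases plus an A73 — so both
readings are parsed and the one with the cleaner acceptor stem wins unless
the caller asserts `expect_cca`. Parsing fails explicitly at more than two
non-canonical stem pairs; no guess is ever returned. This frame yields
every position the identity checks consume (2, 3, 34–36, 70, 71, 73); tRNAs
with long variable arms may defeat the loop heuristic, which is the main
known limitation. Identity elements scored: Ala — G3·U70 and A73; Gly —
C2:G71, G3:C70, C35, C36.

## Editing caller

A site is edited when the modal base differs from the reference and carries
strictly more than half of the counted reads; exact 50/50 splits are
`ambiguous-tie` and depth below `min_depth` (default 4) is `uncovered`.
The conservative majority rule trades sensitivity at marginal depth for a
negligible false-positive rate at any realistic error rate (< 2 %).
Homopolymer indel repairs are not called automatically; an explicit patch
list is applied instead, since a frame-shift "correction" is a curation
decision, not a statistical one. Codon effects of each applied edit are
classified (synonymous / missense / stop-removal / stop-gain /
outside-CDS) under a caller-chosen code table, and a site inside two
overlapping CDSs is reported for both.

## Synthetic data: what it emulates and what it does not

Reference taxa diverge from a common ancestral protein on a star phylogeny:
each taxon substitutes each variable site independently with probability
`substitution_prob` (default 0.15), drawing replacements uniformly from the
other 19 amino acids; a `conservation_floor` fraction of sites (default
0.40, matching the strongly invariant cores of organellar marker proteins)
is held identical across all taxa. Only column-conservation statistics
matter to the inference, so no rate heterogeneity, exchangeability matrix
or tree structure is modelled. Alignments are gap-free by default
(`attach_focal` covers the gapped path and is tested separately), and
amino-acid frequencies are uniform.

The focal genome back-translates the focal protein under the configured
code. Codons whose meaning differs from the standard code are placed only
at invariant sites (`plant_at_conserved`, default on) and are up-weighted
3× over their standard synonyms, reflecting the strong usage bias real
reassigned codons show (a reassigned UGA can outnumber UGG severalfold).
Each configured stop codon terminates at least one CDS when the gene count
allows — a genome whose code includes a termination codon it never uses
would make that codon undetectable in principle, as happens with genuinely
UUR-free genomes. Editing corrupts the genomic sequence at random coding
positions at `editing_site_rate`, with pileups supporting the mature base
at Poisson depth and uniform sequencing error.

Consequently, passing recovery tests demonstrate that the decision rules
are correct and well-calibrated under idealized alignment and conservation
structure; they do not establish robustness to misalignment, compositional
bias, heterotachy, or annotation error in real genomes.

## Problem sizes and numerics

Default study conditions are 15 genes × 200 codons, 20 reference taxa
(narrow panel: first 8 taxa), divergence 0.15; recovery and accuracy
summaries aggregate 20 independent seeds, and the editing benchmark uses
4-gene genomes at mean depth 30 and error 0.02. All randomness flows from
one integer seed through `numpy.random.default_rng`; identical
configurations are byte-identical. The profile aligner (`attach_focal`)
uses expected BLOSUM62 column scores with affine gaps (open −10, extend −1)
and scores `X`/`*` as 0; traceback prefers matches, resolving degenerate
optima deterministically.

## Design choices that were genuinely open

- AUA in the Marsupiomonadales mitochondrial table defaults to `X`
  (unresolvable from the data) and is overridable; forcing AUA→Met for
  protein export is exposed as an explicit configuration override, never an
  inference outcome.
- Lineage-specific ORFs (names like `orf761`) are excluded from profiling
  and codon counts by default: conservation-based inference is only
  meaningful on conserved genes. A flag re-includes them.
- Codon-usage tables exclude the annotated terminal codon by default
  (internal usage is what codon-meaning analyses consume); terminal counts
  are kept separately and mergeable by flag.
- `insufficient-evidence` codons keep their standard meaning in
  retranslation: only codons that meet the trigger are re-interpreted.
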