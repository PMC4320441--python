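# Methods

## Scope and model

`spliceimpact` annotates the protein-level consequences of differential
alternative splicing events. It does not discover events: the event table
(probeset/event id, gene, genomic region, event class, host transcript,
splicing-index and fold-change metadata) is an input, as produced by an
upstream differential-exon analysis. SI and FC are carried through as
metadata and never recomputed.

All internal coordinates are 0-based half-open (genomic intervals and residue
intervals alike); file formats keep their native conventions — GTF/GFF3 and
the domain TSV are 1-based inclusive on disk and converted exactly once at
read/write time. Gene symbols are matched case-insensitively after trimming,
since mouse-style (`Egfr`) and human-style (`EGFR`) symbols routinely coexist
in annotation sources. CDS intervals include the stop codon internally;
translation stops at the first in-frame stop regardless, so either GTF
convention is accepted.

## Isoform pair construction

Each event is attached to a host transcript by an explicit
`host_transcript_id`; when absent, the fallback host is the gene's transcript
with the longest CDS (ties: lexicographically smallest id) — a deterministic
stand-in for the manual "most representative transcript" choice an analyst
would make. The inclusion/exclusion pair is then synthesized per event class:

* `skipped_exon`, `alt_5ss`, `alt_3ss` — exclusion = host minus the region,
  exon boundaries trimmed (alternative splice sites are sub-exon regions
  abutting an exon edge, so trimming, never whole-exon deletion);
* `intron_retention` — the host is the exclusion form; the inclusion form
  merges the fully intronic region into its flanking exons, and the region
  becomes coding when CDS runs up to both intron boundaries;
* `alt_promoter` / `alt_polyA` — exclusion drops the region plus all exonic
  sequence transcript-upstream / -downstream of it;
* `complex` — no synthesis: both transcripts must be annotated and are named
  as `"INCLUSION_ID|EXCLUSION_ID"` in the host field. (How composite events
  should be paired is not derivable from a single host, so the package makes
  the choice explicit input.)

The region is classified against the inclusion CDS projection as
coding / utr_only / mixed (not_determined for non-coding inclusion). UTR-only
events are **not** discarded at this stage: alternative terminations through
non-coding exons can still change the protein, so protein change is always
decided downstream by translation, not by region class.

## Translation and residue diff

The spliced mRNA is translated with the standard genetic code from the
annotated start codon to the first in-frame stop, reading past the annotated
CDS end into the 3' UTR when a frameshift removed the original stop. If the
event removed the annotated start codon, the mRNA is rescanned for the first
AUG opening a reading frame of ≥ 30 codons (else the isoform is called
non-coding). The 30-codon floor screens out spurious micro-ORFs while
accepting any biologically plausible rescue product; it is this package's
explicit substitute for the undefined manual judgement of such cases.
A stop codon falling more than 50 nt upstream of the last exon–exon junction
(the standard NMD heuristic) sets an informational `premature_stop_flagged`
status that feeds no downstream filter. Unknown nucleotides translate to `X`
with a warning; selenocysteine and non-standard code tables are unsupported.

The two proteins are compared as whole sequences — longest common prefix,
then longest common suffix of the remainders, capped so prefix + suffix never
exceeds the shorter length. No alignment algorithm is used: prefix/suffix is
deterministic, captures in-frame deletions exactly (an in-frame deletion of k
codons with distinct flanks gives `n_altered = k`), and treats
frameshift-divergent tails as altered blocks, which is the intended
semantics. `frac_altered` uses the *longer* protein as denominator, keeping
it in [0, 1] and matching "% of full-length protein" when the full-length
form is the longer one.

## Domain impact

Domains (accession, name, free-text description, residue interval) are
annotated on the inclusion (reference) protein only; domain gains present
only in the exclusion isoform are out of scope — they would require
re-scanning the minor isoform with an HMM/PSSM engine, which this package
deliberately does not do. The residue correspondence implied by the diff is
piecewise trivial (prefix identity, suffix offset, altered block absent), and
each domain is called:

* `lost` — every domain residue absent from the exclusion isoform;
* `truncated` — no conserved suffix and the conserved sequence ends strictly
  inside the domain (protein shortened into the domain);
* `internally_altered` — some but not all domain residues in the altered
  block; frameshift-divergent residues count as altered, because a divergent
  sequence cannot preserve the domain;
* `intact` — no overlap with the altered block.

Events that change the protein but no domain are placed positionally:
n_term if the whole altered block precedes the first domain start, c_term if
it follows the last domain end (pure truncations/extensions included), else
linker. Zero-domain proteins use the block position itself (touching residue
0 → n_term, checked first; touching the last residue or beyond → c_term;
otherwise linker), keeping the classification vocabulary total.

## Overlap filter

A gene whose changed domain relates to its annotated function is flagged by
plain word overlap: tokens are lowercase alphanumeric runs, single-character
tokens are dropped, and a shipped ~80-word stopword list (conjunctions,
prepositions, articles; overridable by config) is removed. Only descriptions
of **changed** domains participate. No stemming, lemmatization, synonym
expansion or GO-graph traversal is applied — exact token equality only, so
"ions" ≠ "ion". Term *names* are compared; GAF 2.x input carries GO IDs
rather than names, so the two-column `gene<TAB>term-name` TSV is the primary
GO format for this filter. Genes absent from the GO annotation fail the
filter with a warning rather than erroring.

## Enrichment

One-sided (over-representation) Fisher's exact test per pathway:
`p = P(X ≥ k)` for `X ~ Hypergeom(N, K, n)` via the scipy hypergeometric
survival function (log-space internally). The default universe is the set of
genes in the GO annotation input — the most defensible background when the
original screening platform's background is unknown — and is configurable.
No multiple-testing correction by default (significance is plain `p ≤ 0.01`);
Benjamini–Hochberg is available behind a flag. Results are sorted by
ascending p, ties broken by descending k then pathway id, so the "most
affected pathway" is always well-defined.

## Synthetic fixtures

The generator (`spliceimpact.synth`) builds each gene in mRNA space first —
5' UTR, start codon, body codons, stop, 3' UTR, then exon cut points and
introns — and lays it onto its own contig, reverse-complemented for
minus-strand genes (strands alternate). Two construction rules make planted
truth analytic:

* all non-planted sequence is drawn from the `{C, G, T}` alphabet, so ATG and
  stop codons exist only where planted;
* planted deletions/insertions are multiples of 3 nt, so fixtures contain no
  frameshifts (frameshift handling is exercised by hand-built unit
  fixtures instead).

Truth labels (region class, protein/domain change, affected region, overlap
pass) are computed at generation time from the generator's own mRNA-space
sequences with its own per-residue logic — independent of the pipeline's
genomic-coordinate path, so end-to-end label recovery is a genuine test of
GTF/FASTA round-tripping, pair building, splicing, translation and liftover.

Defaults emulate a differential-splicing screen of a few hundred events:
236 genes (one event per gene); event mix dominated by exon skipping with
prominent alternative promoter/polyA classes
(0.30/0.08/0.08/0.12/0.14/0.18/0.10 over skipped_exon, alt_5ss, alt_3ss,
intron_retention, alt_promoter, alt_polyA, complex); ~10% of exon-skipping
placements in the 3' UTR; `frac_domain_affecting = 0.53` and
`frac_overlap_pass = 0.38`, matching the stage-to-stage survival rates such
screens report; genes of 61–151 codons with 3–10 exons (desk-scale sequences
keep the suite fast without changing any code path). The planted pathway has
15 members of which 10 are drawn from the overlap-passing genes plus 10
random decoy pathways — a design-time power analysis: with ~35–45 passing
genes in a 200–236-gene universe, 10/15 planted hits yield p ~ 1e-5 to 1e-8,
detectable at the 0.01 threshold with large margin across seeds, while decoys
stay near chance. Small test fixtures scale the planted pathway down
explicitly.

What the fixtures do **not** emulate: real gene structures and lengths,
expression noise, frameshifting events, overlapping genes, alternative
transcripts beyond the pair under test, and real domain/GO vocabularies
(fixture vocabularies are token-disjoint by construction so the overlap
truth is unambiguous). Passing the end-to-end test therefore demonstrates
correct mechanics of the funnel, not robustness to annotation noise in real
genomes.

## Numerical and degenerate-input choices

* Interval arithmetic is exact integer arithmetic on half-open intervals; no
  tolerances anywhere in coordinate handling.
* Fisher p-values: scipy's survival function agrees with exact integer
  enumeration to < 1e-10 over the tested grid (N ≤ 60).
* Empty exclusion protein ⇒ every inclusion residue absent
  (`frac_altered = 1`); two non-coding isoforms ⇒ no protein change; events
  whose host cannot be resolved or whose region violates its class's
  preconditions are excluded with a reason code and logged, never fatal.
* Determinism: a single seeded generator stream per fixture; pipeline outputs
  are byte-identical for identical inputs (sorted tie-breaks everywhere).

## Replay mode

`replay_table_s2` aggregates a *recorded* per-event annotation table
(flexible column aliases; truthy flags) into funnel counts without
recomputing translations or domains. This is the honest way to reproduce
published counts that depend on a historical annotation snapshot: stage
recomputation against current RefSeq/CDD/GO content would legitimately give
different numbers. The test suite exercises the adapter on a synthetic
stand-in table carrying a published screen's marginals.

## Known limitations

* Domain gains in the exclusion isoform are invisible (no re-scan).
* The overlap filter is purely lexical; semantically related but
  token-disjoint descriptions ("phosphotransferase" vs "kinase activity") do
  not match.
* Mutually exclusive exons and other composite events must be supplied as
  explicit `complex` transcript pairs.
* The enrichment background is only as good as the supplied GO/gene universe;
  no correction for gene length or annotation bias.
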