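# Methods

This package reimplements the classic genome-survey workflow for the basic
helix-loop-helix (bHLH) transcription-factor superfamily: find every
candidate bHLH motif in a set of genomic contigs, decide which candidates
are bona fide family members, assign each member to one of the 45 named
animal bHLH families (binned into high-order groups A–F plus an "orphan"
category), and map the introns that interrupt the motifs.  Everything runs
offline: the published reference motif sets are pluggable FASTA inputs, and
a synthetic stand-in catalog plus a synthetic-genome generator make every
stage testable without downloads.

## The motif model

The bHLH domain is modelled as a ~60-residue unit partitioned into four
contiguous sub-regions — basic (DNA binding), helix 1, loop, helix 2 — with
default half-open boundaries (0, 13), (13, 28), (28, 42), (42, 60) in
profile coordinates, scaled proportionally for shorter motifs.  Nineteen
alignment positions are designated *conserved sites*.  Their identity is a
convention of this package (the two historically most conserved motif
positions, sites 23 and 59 in 1-based coordinates, are included, and the
remainder are distributed over the basic region and both helices, leaving
the variable loop nearly free, which matches how conservation is
distributed across the domain); the positions and the consensus cutoff
(default: residue frequency ≥ 0.5 among references) are configuration,
not hard-coded facts.

## Reference sets

Two reference collections drive the survey, mirroring common practice: a
*representative* set with one motif per family, used to seed the genomic
scan, and a *full* set of 114 motifs whose per-family counts mirror the
mouse repertoire, used for ortholog assignment.  When no published FASTA is
supplied, both are synthesized deterministically: each family receives a
characteristic motif by substituting the 60-residue consensus at
non-conserved positions with probability 0.5 (between-family divergence),
and each member of a family is an independent perturbation of the family
motif at rate 0.2.  Every member carries private substitutions — there is
no extant "ancestral" member — because a family whose first member *is* the
family consensus would sit on a zero-length branch and could never be
resolved as a bootstrap-supported partner, an artifact real paralogous
families do not show.  Within-family divergence of 0.2 reflects
paralog-level divergence of real animal bHLH families (family members are
ancient duplicates, typically 20–40% diverged across the motif), distinctly
above the ortholog-level noise the pipeline must tolerate (~5%).  The 19
conserved sites carry the consensus residues in every synthetic reference.
A single highly diverged motif (80% substitution) serves as the outgroup
that roots every in-group tree, standing in for the rice R-family motif
conventionally used for this purpose.

## Synthetic genomes

The generator plants family-labelled genes in i.i.d. background sequence
(default GC 0.42) and records exact ground truth.  A planted gene is a
reference motif mutated at per-site rate 0.05 (the 19 conserved sites
protected), reverse-translated with a fixed most-frequent-codon table, and
split by 0–3 introns inserted at codon boundaries.  Intron counts follow
the frequencies of the surveyed repertoire (60/26/19/2 of 107 members with
0/1/2/3 motif introns); intron lengths are log-uniform on [60, 3000] bp —
short enough to keep simulated contigs small while exercising the same
splice geometry as real tables, whose motif introns run from 82 bp to
45,217 bp.  Introns carry realistic boundary signals: the extended donor
consensus `GTAAG`, a polypyrimidine tract, and the terminal `AG`.  Genes
land on either strand (minus-strand genes as reverse complements, with
coordinates recorded in descending order so that the printed-table gap
formula `|downstream_start − upstream_end| − 1` holds on both strands).
One gene is placed per contig with ~400 bp flanks.  Ground truth is written
as GFF3 plus a TSV shaped like the survey's coding-region table.

What the generator does *not* emulate: repeats, pseudogenes, paralog
clusters, split codons at intron boundaries, non-canonical splice sites,
sequencing gaps, and base-level ambiguity.  Passing the recovery tests
therefore shows the pipeline's logic is correct under clean conditions, not
that it is robust to assembly artifacts of real genomes.

## Translated scanning and splice-aware chaining

Instead of calling an external search tool, contigs are scanned directly:
each reference motif is slid over all six reading frames with an ungapped
PAM250 log-odds profile (prefix-score tables make this one vectorised pass
per query and strand).  Contiguous placements above the (deliberately
permissive) score threshold are reported as single-segment candidates —
the survey's contract at this stage is to keep *everything* bHLH-related
and let the downstream filter decide.

Intron-interrupted motifs are reconstructed by chaining: a dynamic
programme over query split points places each query piece independently,
requiring canonical `GT..AG` boundaries at codon-aligned positions, gap
lengths within [60 bp, 50 kb] (the ceiling comfortably covers the longest
motif intron on record, 45,217 bp), and at most three introns.  Each chain
pays a fixed per-intron penalty (15 score units), so a contiguous placement
wins whenever one explains a locus, and earns splice-signal bonuses — 2 per
matching base of the extended donor consensus and 1 per pyrimidine in the
8-base window before the acceptor — which disambiguate true boundaries from
chance `GT..AG` pairs, the same information splice-site predictors
exploited in the original workflow.  Chaining is only attempted for
queries with a quarter-block anchor (some 15-residue block scoring ≥ 50% of
its self-score): with at most three introns at least one block of a split
motif is intron-free, so the gate cannot lose a recoverable locus, and it
skips the expensive DP on almost all query/contig pairs.  Hits sharing a
contig, strand, and overlapping coding regions are deduplicated to the
single best-scoring interpretation.

## The conserved-site filter

Candidates are aligned globally (free end gaps, PAM250, gap open −10,
extend −0.5) to the reference consensus, and their residues at the 19
conserved sites are compared with the profile's consensus sets.  The
historical two-stage rule is applied exactly as stated: stage 1 keeps
candidates with fewer than nine variations; stage 2 discards candidates
with fewer than ten conserved residues.  Over the same 19 sites the two
thresholds are not equivalent (stage 1 already implies ≥ 11 matches), so
stage 2 is logically subsumed; the implementation keeps both stages and
logs when stage 2 would have acted, preferring fidelity to tidiness.  Sites
aligned to a gap count as variations.  Accepted candidates receive a total
basic/helix1/loop/helix2 region map by projecting the template through the
alignment (insertions extend the region they fall in).

## Phylogenetic engine

*Distances.*  Pairwise distances between aligned motifs are per-column
costs from a symmetric step matrix derived from the Dayhoff PAM250
log-odds matrix — `cost(a,b) = (S(a,a)+S(b,b))/2 − S(a,b)`, so identities
cost zero and radical replacements cost most — normalised by the number of
mutually ungapped columns.  The exact historical step-matrix file is no
longer distributed; this derivation preserves its contract (a fixed
symmetric amino-acid cost table) and is documented rather than shipped as
an opaque fixture.

*Neighbor joining.*  Standard Saitou–Nei with a deterministic
smallest-index tie-break and branch lengths clamped at zero.  On additive
matrices it recovers the generating tree exactly (tested against 100
random trees and cross-checked against scikit-bio's implementation).

*Maximum parsimony.*  `max_parsimony` is an exact branch-and-bound
minimisation of the Fitch length (site patterns compressed, partial-tree
lengths as monotone bounds, lexicographic tie-break), practical to 12
taxa.  Inside bootstrap loops a deterministic heuristic is used instead —
greedy stepwise addition plus leaf re-insertion passes, with insertion
scored incrementally from directed Fitch state sets (one vectorised
operation per edge) — mirroring the heuristic-search parsimony of the
original protocol at a small fraction of the cost.

*ML-surrogate.*  The third method applies neighbor joining to
maximum-likelihood distances under the 20-state equal-frequency Markov
model, d̂ = −(19/20) ln(1 − 20p/19).  It replaces quartet-puzzling
maximum likelihood, which contributes its method-diversity role in the
decision procedure rather than its specific optimizer; the in-group trees
are small and the decision logic, not the ML machinery, is the substance
being reproduced.  No empirical amino-acid rate matrix is embedded, so the
equal-frequency model is used rather than shipping a third-party table.

*Bootstrap.*  Support is the percentage of column-resampled replicate
trees containing a bipartition (anchored on the outgroup side), fully
reproducible for a fixed seed.  Defaults: 1,000 replicates for the
distance methods, 100 for parsimony.  For the distance methods all
replicate matrices are produced by one matrix product over a fixed
per-column cost tensor, and replicates run through a join-schedule-only
neighbor joining, which keeps a full three-method analysis of an 11-taxon
in-group under two seconds.

## Ortholog assignment and categories

A global neighbor-joining tree over all accepted candidates, the full
reference set and the outgroup guides in-group selection: walking rootward
from a candidate's leaf, whole families are collected in order of
encounter until at least eight reference members are gathered.  Each
candidate is then analysed with NJ, MP and the ML-surrogate.  Per method
the candidate either forms a two-taxon clade with a unique reference under
the outgroup root (`mono_with_partner`, with the clade's bootstrap), forms
a clade with all present members of one family but no single member
(`n/m*`), or shows no family-level monophyly (`n/m`).

Categories count methods supporting the same partner with bootstrap
strictly above 50 (a support of exactly 50 is weak): three such methods is
category 1; exactly two is category 2 (the sub-pattern — which method was
weak — is preserved); at least one method finding the partner but fewer
than two strong is category 3; no partner in any method is category 4,
which triggers a rerun on whole-protein sequences when they are supplied
(the synthetic path fabricates none by default; the mechanism is
injectable).  This rule is total and monotone: raising any bootstrap never
demotes a category.  Applied to the packaged transcription of the printed
gene listing it reproduces the published census of 83 fully supported
members and 4 whole-protein fallbacks; the strict reading of "above 50"
places one borderline member (support exactly 50) in category 3 where the
original text grouped it with category 2.

## Intron analysis and the printed-table fixtures

Intron lengths derive from consecutive reading-order coding segments as
`|downstream_start − upstream_end| − 1`; the interrupted residue is
`cumulative_exon_bp // 3`, and an intron falling exactly between codons
belongs to the region of the downstream residue (a deterministic tie-break
consistent with single-region labels in printed tables).  Structures
spanning two contigs yield no introns and are flagged.

The packaged TSV transcriptions of the survey's two printed tables are the
fixture-mode input.  Every printed intron length is re-derived from the
printed coordinates as a validation pass.  Ten rows of the source table
are internally inconsistent: two genes carry self-evidently damaged
coordinates (`GpNPAS3`, `GpAHR1`; no intron annotations), and eight printed
intron lengths disagree with the printed coordinates of their flanking
segments (enumerated with their derived values in
`bhlh_survey.introns.PRINTED_ANOMALIES`; several look like single-digit
transcription damage).  These rows are carried verbatim and excluded from
coordinate validation via the explicit skip-list; all 62 self-consistent
rows validate exactly.  Summary statistics use the printed lengths
throughout, so the published aggregates (47 members with introns, 70
introns, longest 45,217 bp, mean 4,393 bp, and the per-region breakdowns)
are reproduced unaffected.

## Problem sizes and numerical choices

The recovery experiments use 20 planted genes per genome at substitution
rate 0.05 across ten seeds — large enough to exercise every intron
configuration and most families, small enough that the full pipeline
(scan, filter, three-method bootstrap assignment, intron derivation) runs
in about half a minute per genome.  Alignment scoring is float32 in the
scanner and float64 elsewhere; score ties in the scanner resolve by
genomic position, in neighbor joining by smallest index, in parsimony
lexicographically.  Degenerate inputs (empty reference FASTA, background-
only genomes, all-gap column pairs, sub-half-length candidates,
multi-contig structures) are either warned about, rejected with named
errors, or flagged, as documented per function.

## Known limitations

- The scanner assumes ungapped exon alignments; a candidate with a true
  coding indel relative to every reference is found but its boundaries may
  be inexact (the filter's gapped profile alignment still evaluates it).
- Splice boundaries are constrained to codon-aligned `GT..AG`; split
  codons and non-canonical sites are not reconstructed.
- The ML-surrogate is not quartet-puzzling maximum likelihood; supports
  from it are systematically the most conservative of the three methods.
- The agree/differ annotation split depends on name-synonymy judgements;
  only the hypothetical-protein and accession-class counts are treated as
  exact statistics.
- Category 4's whole-protein rerun requires caller-supplied sequences;
  the survey's printed fallback members are represented in fixture mode
  by their footnote flag.
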