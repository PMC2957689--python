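# Methods

## The two-stage model

`domortho` treats ortholog detection as a constrained matching problem.
Stage 1 builds an equivalence relation over all input proteins: two proteins
are candidate homologs iff their domain architectures — the ordered N→C
tuples of domain identifiers surviving filtering — are identical. Stage 2
resolves orthology inside each equivalence class by reciprocal best hits
(RBH) against one or more anchor genomes. The assumptions this encodes:

* Domain composition and order are conserved under stronger functional
  constraint than primary sequence, so architecture identity is a reliable
  (and cheap) homology signal even between distant species.
* Within a homolog group, the highest-scoring cross-species pair is the
  orthologous one; in-paralogs lose the race, so only the most similar
  in-paralog enters a reported group (the rest remain in the same homolog
  group but unreported).
* Orthologs whose architectures differ — after domain rearrangement,
  insertion, or deletion — are undetectable *by construction*. The test
  suite demonstrates this on simulations with a forced rearranged lineage.

## Stage 1: architectures

Domain hits are read from 12-column BLAST-style tabular files (query =
protein, subject = profile). Profile accession versions are stripped
(`PF00085.14` → `PF00085`) so architectures are stable across database
releases. Processing per protein:

1. **E-value filter** — keep hits with E-value strictly below `evalue_max`
   (default 0.01; "below" is read as a strict inequality).
2. **Overlap resolution** — hits are admitted greedily by ascending E-value
   (ties: descending bit score, then lexicographic domain id, then start);
   a hit is discarded if it overlaps an admitted hit by more than
   `overlap_fraction` (default 0.5) of the shorter hit's span. Greedy
   flattening is deterministic and idempotent; on instances of ≤8 hits the
   tests verify feasibility and maximality against exhaustive subset
   enumeration.
3. **Ordering** — surviving hits sorted by start (ties: end, then domain
   id) give the architecture. Tandem repeats are significant
   (`A/A/B ≠ A/B`); no hits gives the uncharacterized sentinel.

Proteins partition into homolog groups keyed by exact architecture; all
uncharacterized proteins share a single group, processed identically by
stage 2 (a `uncharacterized_cap` option can skip it, since that pool can
approach whole-proteome scale on real data).

## Stage 2: within-group RBH

For each anchor species and each homolog group, every anchor protein is
scored against the group's members of every other species. "Best" is
ordered by bit score (desc), E-value (asc), then protein id — the last key
makes runs deterministic. Protein *b* of species *S* joins anchor protein
*a*'s group iff *b* is *a*'s best hit within *S*'s group members and *a* is
*b*'s best hit among the anchor's group members. Groups need ≥ 2 species
(`min_species`); anchor proteins with no reciprocal partner are logged and
dropped. Because the best-partner relation is single-valued, no protein
joins two groups under one anchor.

**Similarity backends.** The default backend is Smith–Waterman local
alignment via Biopython's `PairwiseAligner`: BLOSUM62, gap open 11, extend 1
(Biopython's convention — a length-L gap costs 11 + (L−1)), residues outside
the BLOSUM62 alphabet aligned as `X`. Raw scores are converted to bits with
Karlin–Altschul scaling, bits = (λS − ln K)/ln 2 with λ = 0.267, K = 0.041
(the standard gapped BLOSUM62-11/1 parameters), and E = m·n·2^(−bits) for
one pairwise comparison. Only positive-scoring pairs count as hits; an
optional bit-score threshold can discard weak ones. Alternatively a
precomputed pairwise tabular file supplies the scores (`tabular:PATH`);
pairs absent from the file are no-hits (the best row per unordered pair is
used so both directions are scorable).

**Multiple anchors.** Candidate groups from different anchors are merged by
connected components over shared members (only groups from the same homolog
group can ever share a member, so architectures stay consistent). If a
merged component would carry two proteins of one species — possible only
when a group holds several same-species paralogs — the protein with the
higher summed bit score to the component's anchor proteins is kept and the
conflict logged. The merged group is seeded by the lexicographically
smallest anchor protein. IDs are assigned after merging: `PfamArcNu<k>` for
domain-based groups, `NoDomainInfo<k>` for groups from the uncharacterized
pool, counters running in anchor-protein-id order. The architecture map
(`PfamArcMap.txt`) numbers homolog groups independently, sorted by
architecture string.

## The synthetic generator

`simulate(SimConfig)` evolves `n_families` gene families over a balanced
binary species tree with unit branch lengths. Per family: an ancestral
architecture (ordered draw from a `domain_alphabet_size`-letter domain
alphabet, by default unique per family; each domain has a global consensus
sequence of 60–120 residues, linkers of 5–25). Per branch and per gene
lineage, independently: loss with `p_loss`, duplication with
`p_duplication`, one architecture rearrangement (swap adjacent distinct
domains / insert an alphabet domain / delete a domain, always changing the
architecture) with `p_rearrangement`; every residue then mutates to a
different amino acid with probability `substitution_rate` (uniform
replacement, no rate heterogeneity or indels). Defaults are 10 species,
100 families, all event probabilities 0.05, substitution 0.05 per branch —
enough divergence to be visible, far from drowning the within-family
signal.

Emitted domain hits mirror each gene's realized architecture with
coordinates matching domain placement and E-values drawn log-uniform in
[1e−30, 1e−3], i.e. always below the 0.01 filter; `inject_decoys` adds
spurious hits at E ≥ 0.01 that shadow real hits (contained in their target
interval, lower bit score), so the filter and the overlap resolver can be
exercised separately.

**Truth.** Every duplication is stamped with its branch; a gene's trace is
the list of duplication events it inherited. Two same-family genes of
species u and v are recorded as a true ortholog pair iff their traces agree
on all events on branches at or above the u/v split — duplications below
the split are in-paralogs and both copies remain co-orthologs of the other
side, duplications above it make out-paralogs. Truth rows carry per-protein
`duplicated`/`rearranged` flags; `TruthSet.family_partition()` gives the
family-level reference partition.

What the generator does *not* emulate — indels, rate variation across sites
and lineages, convergent architectures, domain-length distributions,
promiscuous domains, horizontal transfer — bounds what green tests mean:
they certify the pipeline's logic (grouping, mutual-best resolution,
merging, determinism) under structurally faithful evolutionary events, not
its accuracy on real proteomes, where domain-call quality dominates.

## Evaluation metrics

`compare_partitions` scores a predicted partition against a reference:
exact-match fraction (predicted groups identical as member sets to some
reference group), majority-overlap fraction (strictly more than half of a
predicted group's members inside one reference group — so exact ≤ majority
always), and precision/recall over unordered cross-species member pairs
(swapping predicted and reference exchanges precision and recall). The
species-count histogram and the cost model — C(n,2) all-vs-all genome
pairs; updating with m new genomes costs n·m pair comparisons for
conventional RBH but only m domain scans here — complete the picture.

Taxonomic *closeness* of a group is the mean over unordered member-species
pairs of depth(LCA)/depth(deeper leaf) on a supplied rooted newick taxonomy
(depths in edges from the root); identical species score 1, species sharing
only a depth-0 root score 0. This ratio is this package's own
formalization of "how taxonomically tight is this group" — monotone in
relatedness, 1 for single-species groups. A two-sided Wilcoxon rank-sum
wrapper (`rank_sum_test`) supports comparing closeness or gene-length
distributions between two sets of groups.

## Numerical and design choices

* All orderings (group members, IDs, tie-breaks, file output) are total, so
  fixed inputs give byte-identical outputs across runs.
* The reference-partition TSV carries three columns (group id, species id,
  protein id): pair-level metrics need species identity.
* Species labels come from the run configuration, never from FASTA headers;
  terminal `*` stop characters are stripped on read, all other residue
  characters kept verbatim.
* Genome-wide-RBH equivalence (used as an oracle in tests and the
  acceptance script) holds exactly when architectures are unique per family
  *and no gene loss occurred*: a loss can orphan a gene whose genome-wide
  mutual best then lands in a different family — a pairing this pipeline
  deliberately refuses. A regression test pins a seed exhibiting that
  divergence; the equivalence checks run loss-free (duplication kept, since
  in-paralogs stay within their family).
* Multi-anchor coverage monotonicity is checked on loss-only simulations:
  that is the scenario the multi-anchor mechanism exists for, and with
  same-species paralogs absent the merge's conflict rule (which may drop a
  protein, with a log entry) never fires.
* Problem sizes in tests and the acceptance script (≤10 species, ≤100
  families, 200 random oracle groups, 50 monotonicity simulations) are
  chosen so the whole battery completes in seconds while every code path —
  including merging, paralog conflict, and the uncharacterized pool — is
  exercised.

## Known limitations

Orthologs with differing reported architectures are undetectable; the
uncharacterized pool degrades to plain RBH; only the best-scoring in-paralog
is reported per species; domain-call quality (here simulated as perfect
below the E-value cutoff) upper-bounds real-world accuracy; the builtin
aligner's E-values are per-pair, not database-corrected, and are used only
for ranking.
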