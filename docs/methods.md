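# Methods

This note documents the models, numerical choices and limitations of
`lecatrace`, in the spirit of the methods documentation of packages
like statsmodels or msprime: what is computed, under which assumptions,
and what the tests do and do not demonstrate.

## Pairwise comparison

All protein comparisons use BLOSUM62 with affine gap costs of 11 to
open and 1 to extend (a gap of length *k* costs 11 + *k*, the blastp
default regime).  Two statistics are computed per pair:

* **Global percent identity** from a Needleman–Wunsch alignment with
  end gaps penalized.  Identity = identical aligned residue pairs ÷
  total alignment columns, *including* gap columns — the strictest of
  the common conventions; the choice is pinned here because published
  descriptions of "global identity" rarely print the denominator.
  Among co-optimal alignments the traceback is made exactly symmetric
  by aligning the lexicographically smaller sequence first.
* **Local bit score** from Smith–Waterman, transformed by the
  Karlin–Altschul relation S′ = (λS − ln K)/ln 2 with the published
  gapped BLOSUM62 constants λ = 0.267, K = 0.041.  A raw score of 0 (no
  positive-scoring local alignment) is reported as 0 bits: the
  transform is not meaningful there.

E-values use E = m·n·2^(−S′) with n = the total residue count of the
subject set *at call time*.  This makes the statistic deterministic and
self-contained, at the price of absolute E-values that depend on the
pool being searched; only the threshold semantics (E ≤ 10⁻¹⁰ for
clustering, E ≤ 10⁻⁵ for hit profiling, both combined with identity
≥ 25%, all bounds inclusive) are meant to be portable.  The dynamic
programming itself is delegated to Biopython's `PairwiseAligner`; an
independent pure-Python Gotoh implementation in the test suite verifies
both modes on random sequence pairs.

## Family clustering

Reciprocal best hits are computed **per proteome pair**: for each
ordered pair of proteomes, each query's best passing hit (highest bit
score, ties by lower E-value then lexicographically smaller subject id)
is found in the other proteome, and a pair {a, b} becomes an edge when
the choice is mutual.  This is the classic RBH orthology construction:
a protein can hold one partner per other proteome, so an *n*-taxon
family forms a dense subgraph rather than a matching.  Edges are
weighted with 100 × global identity.  Proteins with no RBH never enter
the graph and are reported as *unclustered*, not as singleton families.

MCL is implemented from scratch on the column-stochastic flow matrix:
self-loops at each node's maximum incident weight (the standard
regularisation against bipartite oscillation), then iterated expansion
(matrix power 2) and inflation (entrywise power 2.0 + column
renormalisation) with pruning of entries < 10⁻⁵, until the flow changes
by < 10⁻⁸ or 100 iterations (non-convergence yields a warning and
clusters from the final matrix).  Clusters are attractor systems (rows
retaining positive diagonal mass, unioned when one attractor attracts
another) plus their attracted nodes; a node attracted by several
systems goes to the one with the largest flow mass, ties to the system
whose smallest attractor id is lexicographically least.  Cluster ids
are content-addressed (SHA-1 of the sorted member list), so identical
clusterings get identical ids across runs and input orders.

Bacteria and archaea are clustered separately; eukaryotes are clustered
with the same method and cutoffs.  (In the study this package models,
eukaryotic families came from an earlier publication whose exact
cutoffs are not printed; clustering them identically is a documented
deviation in exchange for a self-contained method.)

## EPC merging, LECA filter, contribution

A eukaryotic cluster E and prokaryotic cluster P merge into an EPC when
≥ 50% of E's members have their best cross-set hit (under the
clustering thresholds) inside P *and vice versa*; "at least 50%" is
inclusive, members without a passing cross-hit abstain but remain in
the denominator, and a tie between two equally supported candidate
partners yields no link (conservative, logged).  Archaeal and bacterial
merges are independent, so categories are EA, EB, or EAB (both).

The LECA filter keeps eukaryotic clusters covering all six supergroups
(Archaeplastida, Opisthokonta, SAR, Hacrobia, Excavata, Mycetozoa); the
asgard-unique set is the EA EPCs whose archaeal partner contains asgard
taxa exclusively.  Percentages are rounded half-up at the presentation
layer only; raw fractions are carried internally.

## Hit profiles and length statistics

For profiling, *all* passing hits count (not only the best one): a
protein's category is the set of domains — E, A, B or any combination —
among its surviving subjects, `none` when no hit survives.  Hits from
the query's own genus are excluded first to counter database
composition bias; `exclusion_rank: phylum` (group-level exclusion)
reproduces the stricter variant as a configuration change.

The two-sample KS statistic D is computed exactly (supremum over pooled
points of the ECDF difference); p-values use the asymptotic Kolmogorov
distribution with effective sample size n_x·n_y/(n_x+n_y), adequate for
the intended sample sizes of hundreds and irrelevant to D itself.  The
BH correction family is all pairwise contrasts emitted in one report.
Box-plot summaries use linear interpolation between order statistics
for quartiles and whiskers at the most extreme points within 1.5 IQR —
both pinned conventions, since box-plot conventions vary.

## Presence–absence matrices

PAP rows are families/EPCs, columns taxa or group labels; in group mode
archaeal groups with fewer than 15 registry members (configurable) pool
into "Other Archaea".  Row order over supergroups sorts by (number of
supergroups present desc, 6-bit presence pattern as a binary number
desc, row key asc).  Hierarchical leaf orders use average linkage on
Jaccard distances for boolean profiles (Euclidean for counts), with
inputs canonicalised by key sort and the deterministic tie rule that
the subtree containing the lexicographically smallest key goes left —
hence orderings are invariant to input shuffling, and identical vectors
end up adjacent.

## Synthetic communities

The generator is the package's testbed: it emulates the statistical
features the analysis relies on, not real genome evolution.

* **Community**: by default 30 taxa — two eukaryotes per supergroup,
  six bacteria across three genera in two phyla, six non-asgard archaea
  in two classes, six asgard archaea each its own genus — and 60
  planted families (10 E, 8 A, 8 B, 10 EA, 10 EB, 10 EAB, 4
  asgard-unique EA).  These sizes keep a full run around half a minute
  on one CPU while exercising every code path, including genus
  exclusion and "Other Archaea" pooling.
* **Sequence model**: star-shaped evolution — one ancestral sequence
  drawn uniformly over the 20 residues at a length uniform in 80–160,
  one substitution-only descendant per seeded taxon.
  `within_family_identity` (default 0.7) is the target *pairwise*
  identity between members; the per-leaf ancestor identity *a* solves
  t = a² + (1−a)²/19 (both leaves unmutated, or both mutated to the
  same alternative residue).  Substitution-only evolution keeps this
  expectation analytic and the truth bookkeeping exact.  Unrelated
  families are independent random sequences, with expected identity
  well under the configured ceiling of 0.1.
* **Seeding**: every participating domain of a family receives at least
  two taxa — a one-member domain side has no within-domain RBH, cannot
  form a cluster and could never be recovered.  EA/EAB archaeal sides
  always include a non-asgard taxon, so asgard-unique families are
  exactly the `EA_asgard_only` profile.  A configurable fraction
  (default 0.5) of E-containing families is seeded into all six
  supergroups and flagged LECA-complete.
* **Orphans**: per taxon, the orphan count is Binomial(number of family
  proteins, `orphan_fraction`); lengths are log-normal, ln-scale
  (5.6, 0.45) for asgard vs (5.0, 0.35) for all other taxa, floored at
  30 residues — planting the "no-hit proteins of asgard archaea are
  anomalously long" contrast by construction.
* **Reproducibility**: each family's RNG stream derives from
  (seed, family id) and each taxon's orphan stream from (seed, taxon
  index), so adding families of one profile never perturbs the
  sequences of others, and a fixed seed gives byte-identical FASTA
  output.

What passing recovery tests show: under separable conditions (pairwise
identity 0.7 within vs ≈ 0.05 between), the search → RBH → MCL → RBC →
LECA chain returns the planted structure exactly (ARI 1.0, exact
asgard-unique and LECA counts).  What they do not show: behaviour on
real proteomes with domain shuffling, indels, BLOSUM-biased
substitution, paralog expansions or horizontal transfer — none of which
the generator models.

## Recovery scoring

Families are planted across domains but clustered per domain (by
design: bacterial and archaeal families are built separately, and a
cross-domain family is only reunited at the EPC stage).  The adjusted
Rand index therefore compares recovered per-domain cluster labels
against (family × domain) planted labels over non-orphan proteins, with
unclustered proteins as their own singletons; orphans are checked
separately (they must receive hit category `none` and join no cluster).

## Problem sizes and runtime

The default community (≈ 510 proteins) implies ≈ 130,000 cached pairwise
alignments; a full pipeline run takes ≈ 30 s and the complete test suite
≈ 30 s beyond that shared run.  The acceptance script's power analysis
uses 100 replicates of 200 lengths per group, where the planted length
contrast is detected in essentially every replicate.

## Known limitations

* Absolute E-values depend on the in-memory subject pool, not a fixed
  database size; only threshold semantics are stable.
* "Best hit" is defined by bit score (ties by E-value, then subject
  id); methods that rank by E-value first may differ on near-ties.
* The asymptotic KS p-value is anti-conservative for very small
  samples; D is exact regardless.
* One prokaryotic cluster may merge with several eukaryotic clusters if
  reciprocity holds for each pair individually; occurrences are logged.
* The MCL implementation covers the algorithmic core (expansion,
  inflation, pruning), not the full option surface of the original
  binary; its resource schemes are mapped to the small prune threshold.
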