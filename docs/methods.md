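# Methods

This note documents the models, parameters and design choices behind
`plasbhr`, in enough detail to interpret its outputs and to understand what
the validation on synthetic data does and does not demonstrate.

## ORF calling

ORFs are called by a deterministic six-frame scan: on each frame of each
strand, an ORF runs from the first start codon (ATG, GTG or TTG — the common
bacterial initiators of translation table 11) following the previous stop
codon, to the next in-frame stop (TAA/TAG/TGA), stop included in the
half-open span. Codons containing N translate as X, and X never terminates
an ORF. ORFs without a stop codon (running off a contig end) are not
reported. Minimum length defaults to 90 nt, a common floor for prokaryotic
gene callers; both the floor and the start-codon set are configurable.

This caller intentionally trades gene-start precision for determinism and
testability: the downstream analysis consumes ORF catalogs for local
homology search, where an imprecise 5' boundary only moves alignment
endpoints, not hit presence. It has no statistical gene model, no RBS
scoring and no partial genes; absolute ORF counts will therefore exceed
those of a trained gene finder (every nested/overlapping start-stop span is
reported, and relevance is left to the homology filters).

Plasmid topology defaults to linear. With `topology: circular` the scan
appends a 3 kb junction-spanning extension so origin-crossing ORFs are
found; these keep `start < length` and `end > length`.

## Homology search

Alignments are exact Smith–Waterman (Biopython's `PairwiseAligner`, local
mode), not a seeded heuristic: at desk scale O(nm) is affordable, and
exactness lets the test suite verify scores against a brute-force
dynamic-programming oracle. Scoring follows BLAST conventions:

* protein: BLOSUM62, affine gaps, a gap of length k costing 11 + k;
* nucleotide: match +2 / mismatch −3, gap of length k costing 5 + 2k; both
  strands of the target are aligned and the better one reported (forward
  wins ties).

Significance is Karlin–Altschul with fixed published gapped parameters
(protein λ = 0.267, K = 0.041; nucleotide λ = 0.625, K = 0.41):
`bitscore = (λS − ln K)/ln 2`, `E = m·n·2^(−bitscore)` with m the reference
length and n the total residue count of the search database. Per-query
composition adjustment and matrix-specific λ recomputation are not
implemented; E-values are therefore BLAST-like, not BLAST-identical. The
filters, not the absolute E-values, carry the scientific weight.

Hit filters are strict inequalities, per category:

| categories                | E-value  | identity | reference cover |
|---------------------------|----------|----------|-----------------|
| REP, TOXIN, ANTITOXIN, RNA_ANTITOXIN | < 1e−5 | > 50 % | > 50 % |
| RELAXASE, T4SS, ARG, VF   | < 1e−5   | > 50 %   | > 70 %          |
| PAR, PSI, MPS             | < 1e−5   | > 80 %   | > 70 %          |
| MTASE                     | < 1e−5   | > 50 %   | > 50 %          |
| ORIT (nucleotide)         | < 1e−5   | > 90 %   | > 90 %          |

Coverage is computed over the reference (aligned reference span / reference
length), because the references are the queries and the ORFs form the
database. Identity counts identical columns over all alignment columns,
gaps included. A 50.0 %-identity alignment fails a "> 50 %" rule. The
Par/Psi/MPS tier is stricter because reference sets for these functions
typically include unverified homologs; the MTase tier and the oriT gates
are package defaults, exposed in configuration. At most one hit — the
optimal alignment — is kept per (reference, target) pair.

For long nucleotide targets the search uses an accelerator: edlib locates
the best edit-distance placement of the reference on each strand, and the
exact Smith–Waterman runs on a window around that placement
(margin = max(60 nt, ref/4)). Whenever a genuine homolog is present the
window contains the optimum and the result equals the full DP (asserted in
the tests); for unrelated sequences the windowed alignment is rejected by
the coverage gate either way. `accelerate=False` forces the full DP.

## Mobility rules and typing

* conjugative ⇔ relaxase present AND T4SS machinery present;
* mobilizable ⇔ not conjugative AND oriT present (default `strict_paper`
  rule). The `relaxase_or_orit` mode also accepts a lone relaxase, since a
  relaxase suffices for mobilization in trans; it is a superset of the
  strict rule;
* non-mobilizable otherwise.

T4SS machinery is a multi-gene apparatus, so a single gene hit is not
enough: the default requires a hit to a VirB4/TraC-class MPF ATPase plus
≥ 3 distinct T4SS reference genes. Both knobs (`t4ss_min_genes`,
`t4ss_require_atpase`) are configurable. Conjugative calls do not
additionally require oriT detection (oriT references are sparse; relaxase +
T4SS is the accepted operational definition of self-transmissibility).

T4SS reference families encode their MPF type and gene as
`<MPFtype>_<gene>`, with `_ATPase` flagging the ATPase (e.g.
`MPFF_traC_ATPase`). MOB type is the family of the highest-bitscore
relaxase hit (ties broken lexicographically); MPF type is the type with the
most distinct gene hits (ties by best single bitscore); Inc types are the
families of all Rep hits, so multi-replicon plasmids keep every type.

## BHR rule and T-AT pairing

The five host-range feature categories are: complete toxin–antitoxin
system, Par, Psi, MPS, MTase. A plasmid with ≥ 3 (configurable) is a BHR
candidate. The T-AT feature requires the cognate pair — a toxin whose
partner antitoxin family (from the reference header dialect
`id|family|partner`) is also hit, as protein or RNA — because a lone toxin
may simply be a secreted effector; a lone-toxin mode exists for
sensitivity analyses. `vf_free_subset` applies the BHR gate first, then
removes candidates carrying any virulence-factor hit.

## Fragment ANI and clustering

ANI is fragment-based (ANIb-style), replacing aligner-binary approaches so
the whole pipeline stays in-process and exactly testable: the query is cut
into consecutive non-overlapping 1 kb fragments (short remnant dropped),
each aligned to the subject with the nucleotide scoring above; fragments
whose alignment covers ≥ 70 % at ≥ 30 % identity count as aligned; ANI is
the mean alignment identity over aligned fragments, in percent, symmetrized
as the mean of the two directions. No aligned fragment ⇒ undefined (NaN),
which never links plasmids.

A prescreen estimates identity from the edit distance of three probe
fragments per strand and skips pairs whose best probe is below 70 %
identity; this only discards pairs far outside the 95 % clustering regime
(pairs between the 30 % fragment gate and the 70 % prescreen would get a
defined but very low ANI without the prescreen — irrelevant for
dereplication, and `prescreen=False` restores the exact behavior).

Clustering at the 95 % threshold uses single-linkage connected components
(the conventional reading of "clustered at ≥ 95 % ANI"); complete linkage
is available. Undefined or missing pairs count as below threshold. Clusters
are numbered 1-based by their lexicographically smallest member.

## Cohort statistics

Kruskal–Wallis uses the tie-corrected H
(`H = [12/(N(N+1)) Σ nᵢR̄ᵢ² − 3(N+1)] / [1 − Σ(t³−t)/(N³−N)]`) with the
χ²(k−1) approximation even at small n; an exact Monte-Carlo permutation
p-value is available behind a flag. Groups whose pooled values are all
identical return (H = 0, p = 1) rather than an error, which matters for
0/1 ARG-presence comparisons. Dunn's post hoc z uses pooled midranks with
the tie term `Σ(t³−t)/(12(N−1))` and two-sided normal p-values,
Bonferroni-adjusted over the k(k−1)/2 pairs (classical Dunn; Holm
available). ARG presence is encoded 0/1 and reuses the same rank machinery.
Cohorts with fewer than two mobility classes skip the comparisons with a
logged notice.

## Synthetic cohorts

The generator's defaults define the package's reference study conditions;
they were chosen once to mirror the qualitative structure of real AR-isolate
plasmid cohorts at a tractable scale and are not re-tuned per experiment:

* n = 60 plasmids, class mix 0.4 / 0.3 / 0.3
  (conjugative / mobilizable / non-mobilizable);
* log-normal lengths with medians 15 / 8 / 4 kb (σ = 0.30/0.35/0.40) and
  floors 9 / 4 / 1.5 kb — real plasmids span ~1–450 kb, but the conjugative >
  mobilizable > non-mobilizable ordering is what the statistics consume, and
  desk-scale alignment favors modest sizes; backbones are extended when a
  draw cannot hold its planted cassettes;
* backbone GC 0.58 / 0.50 / 0.44 (conjugative highest); planted cassettes
  have ~50 % GC, diluting the contrast, hence the wide spacing;
* cassette divergence 0.05 amino-acid substitutions/site; oriT divergence
  0.02 at the nucleotide level (a separate knob because the oriT gate is
  > 90 % nucleotide identity);
* per-feature plant probability 0.65 / 0.45 / 0.15 per class, ARG carriage
  0.8 / 0.6 / 0.2, VF 0.15, Rep 0.95 (second replicon 0.15), relaxase in
  mobilizable plasmids 0.5;
* 3 planted clusters of size 3 at 2 % within-cluster substitution.

Planting conventions: reference proteins start with M; a cassette is an
in-frame TAA guard + reverse-translated coding sequence (uniform codon
choice) + TAA, overwritten into a random non-overlapping slot on a random
strand. The guard pins the ORF start so 0 %-divergence cassettes are
recovered as exactly the planted protein. Divergence substitutes an exact
count of positions (never the initiator), so alignment identity is
1 − divergence by construction. Within-cluster copies substitute only
backbone positions outside planted cassettes: a random in-frame stop inside
a cassette would otherwise silently change the planted class, decoupling
truth from sequence. Whole-plasmid identity between cluster members is
therefore 100 − rate × backbone-fraction percent, comfortably above the
95 % clustering threshold at the defaults.

Cluster seeds are forced to be BHR candidates so that candidate-level ANI
dereplication sees every planted cluster. A single master seed drives
everything; per-plasmid substreams are derived by counter
(`default_rng([seed, stream, index])`), so cohorts are reproducible byte
for byte and stable under `n_plasmids` changes.

What the synthetic validation shows — and what it does not: recovering
planted cassettes at 5–10 % divergence exercises the full detection chain
(ORF calling, alignment, filters, rules) but is easier than real screening,
where homologs diverge non-uniformly, genes overlap, references are
incomplete, and gene fragments abound. Passing on synthetic cohorts
demonstrates internal correctness of the pipeline's logic and calibration
of its statistics, not field sensitivity/specificity against curated
databases. The generator also omits synteny, insertion sequences,
recombination and codon-usage realism by design.

## Numerical and degenerate-input choices

* Ambiguity codes other than N are accepted on input and collapsed to N;
  N is excluded from GC content (all-ambiguous sequences give NaN).
* Score ties in alignment are broken toward the lowest target start, then
  lowest reference start (bounded enumeration of co-optimal alignments);
  forward strand wins strand ties.
* `search_category` skips reference/target pairs that provably cannot pass
  the joint identity x coverage bound (identity ≤ |target|/(cover·|ref|))
  or reach the minimum passing score, and computes scores before tracebacks;
  these are exact prunings, not heuristics.
* ANI of sequences shorter than the fragment size is a validation error;
  the pipeline lowers the fragment size to the shortest candidate instead.
* Plasmid floats in TSV/JSON outputs are serialized at 6 significant
  digits; profile ordering is lexicographic by plasmid id, making runs
  byte-identical.

## Known limitations

* E-values use fixed published λ/K; no composition-based statistics.
* ARG detection is plain homology against a user panel with the VF-tier
  thresholds; curated per-gene cutoffs and resistance-SNP models of
  dedicated ARG tools are out of scope. Likewise MTase detection does not
  model target-recognition sites.
* The ORF caller reports all nested ORFs; ORF counts are not comparable to
  trained gene finders.
* MOB-suite-style host-range rank prediction and plasmid reconstruction
  from draft assemblies are out of scope; inputs are assumed to be
  plasmid-labeled replicons.
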