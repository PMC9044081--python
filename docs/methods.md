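# Methods

`ssn_divergence` reconstructs, at desk scale, the workflow used to ask
whether the gene families of a microbial community are sequence-conserved or
diversifying: all-vs-all local protein alignment, a thresholded sequence
similarity network (SSN), per-family network topology, a
conserved/diversifying/diverged classification, and pairwise dN/dS between
habitats on the conserved cores. Because the community sequences such studies
analyse are not redistributable, the package carries its own codon-level
family simulator; the simulator is first-class, tested code, and everything
downstream is validated against it and against independent brute-force
oracles.

## Pairwise similarity and E-values

`align.local_align` computes the optimal Smith-Waterman local alignment with
affine gaps through Biopython's `PairwiseAligner` (BLOSUM62; gap open 11,
extend 1, with the first gap position charged open+extend, matching BLAST's
convention). No scoring parameters are canonical for this analysis, so the
defaults are the community gapped-BLOSUM62 conventions, exposed on
`ScoringScheme`.

Raw scores map to bitscores and E-values via Karlin-Altschul statistics with
the standard gapped-BLOSUM62 constants λ = 0.267, K = 0.041:

    bitscore = (λ·S − ln K) / ln 2,     E = m·n·2^(−bitscore)

where the search space for a pair is simply `len(a)·len(b)` — no edge-effect
correction. These choices reproduce conventional protein-search E-value
scales, which is what makes the 1e-30 network cutoff meaningful; they will
not numerically reproduce any particular BLAST version's E-values, and only
the downstream network logic should be compared across tools.

Only the single best alignment per pair is kept (no multiple HSPs or sum
statistics). Correctness is established by two independent oracles in the
test suite: a pure-Python three-matrix affine DP checked on 200 random pairs,
and a fully exhaustive enumeration over substring pairs and gap placements at
lengths ≤ 4, which validates the DP oracle itself.

## The network and its statistics

`network.build_network` puts every (length-filtered, > 150 aa) sequence in
the graph and adds an edge when any hit in either direction has E ≤ the
cutoff (default 1e-30), keeping the minimum E-value and maximum bitscore of
the two directions. Isolated nodes are members of the network — they are the
diverged-sequence signal, not noise to drop.

Global statistics use

    average degree  k̄ = 2K/N,      density  D = 2K/(N(N−1)),

plus component and isolated-node counts, the mean clustering coefficient
(degree < 2 nodes contribute 0 — one of several conventions, chosen and
documented here), the characteristic path length (mean over ordered pairs
with a finite path), the percentage of ordered pairs connected by any path,
and Freeman degree centralization. Closeness centrality is the
reachable-count over summed-distance form computed within each component,
with isolated nodes at 0; this is the definition that stays well-behaved on
the heavily disconnected networks this analysis produces. All of these are
verified against direct Floyd-Warshall computations on 200 random graphs.

An optional CD-HIT-style greedy redundancy clustering
(`network.greedy_cluster`, longest-first, identity measured as identical
aligned positions over the shorter sequence) is provided but off by default:
identity clustering and E-value thresholding are deliberately exposed as two
separate, composable steps rather than entangled in one pass.

## Family classification

Families are analysed as induced subgraphs (cross-family edges belong to
neither family, so family node counts always partition N). The
classification rule is the minimal one consistent with how conserved and
diverged families present in an SSN:

* **conserved** — one connected component, zero isolated nodes;
* **diverged** — isolated fraction ≥ 0.5 (configurable);
* **diversifying** — everything between.

The rule is monotone: adding an edge can never demote a family from
conserved. "Core clusters" are components containing sequences from every
sampled habitat; only cross-habitat pairs inside core clusters enter the
dN/dS stage, because those are the pairs for which a habitat-vs-habitat
selection contrast is defined.

Topology-vs-degree curves bin nodes by exact degree (no logarithmic
binning) and are summarised by power-law fits `y = a·x^b` done as simple
least squares of ln y on ln x, reporting the Pearson correlation and r² of
the log-log pairs — the conventional way such curves are annotated. At the
default synthetic scale the curves have too few distinct degrees for a
meaningful fit and the pipeline reports NaN fits; exponent recovery is
instead validated on synthetic power laws (n = 100 points, 5% multiplicative
noise, bias ≤ 0.1 over 50 replicates).

The `shannon_index` / `alpha_transform` utilities are small conveniences for
community-diversity tables. `alpha_transform` implements the literal reading
`10·log10(α)/ln 10` of an ambiguously typeset transform; its output is *not*
comparable to conventional Shannon indices (2.5–3 for these communities) and
it is kept only for completeness.

## dN/dS: Nei-Gojobori with Jukes-Cantor

No single tool is canonical for pairwise selection scans of this kind, so
the estimator is the fully specifiable NG86 counting method, authored from
first principles and frozen against hand enumeration:

* **Sites.** For each codon position, the synonymous fraction is the share
  of synonymous changes among the *non-stop* single-nucleotide changes;
  mutations to stop codons count as neither and the position renormalises,
  so every sense codon contributes exactly 3 sites (e.g. TTT → S = 1/3,
  TGG → S = 0). Pair sites average the two sequences.
* **Differences.** Single differences classify directly; two- and
  three-difference codons average over the orderings of single steps whose
  intermediates avoid stop codons, falling back to all orderings when none
  survive — a convention NG86 leaves open, fixed and documented here.
* **Correction.** p = diffs/sites, Jukes-Cantor d = −(3/4)·ln(1 − 4p/3);
  ω = dN/dS. Pairs with dS = 0 are flagged `dS_zero` and p ≥ 3/4 flags
  `saturated`; neither receives an arbitrary ω, and range summaries use
  status-ok pairs only.

Codon pairing uses a global protein alignment with free end gaps,
back-mapped to codons, dropping columns with a gap in either sequence; for
the simulator's equal-length, indel-free sequences this reduces to
positional pairing. Estimates need ≥ 10 comparable codons.

## The simulator

`simulate.evolve_family` runs a mutation-acceptance codon process on an
ultrametric tree: root codons drawn uniformly from the 61 sense codons;
along a branch of length t (expected substitution attempts per nucleotide
site) the number of proposals is Poisson(3·L·t); each proposal changes one
random nucleotide, proposals creating stops are rejected, synonymous
proposals are accepted with probability 1 and nonsynonymous with min(ω, 1)
(for ω > 1 the synonymous acceptance is scaled to 1/ω so the NS:S acceptance
odds equal ω). This process was chosen over a full rate-matrix simulator
because it is exactly the quantity NG86 estimates — acceptance probability
per proposal class — which makes ω recovery a sharp test rather than a model
comparison. Proposals are uniform over the three alternative bases, which is
precisely the mutation model Jukes-Cantor corrects.

Trees are star or Yule (random pure-birth topology rescaled so every
root-to-leaf path equals the requested height). Three archetypes define the
study conditions:

| archetype    | subfamilies | height (subs attempts/site) | ω   |
|--------------|-------------|------------------------------|-----|
| conserved    | 1           | 0.05                         | 0.2 |
| diversifying | 3           | 0.8 (between), 0.05 (within) | 0.5 |
| diverged     | one per taxon | 2.0                        | 1.0 |

Heights were set from the alignment arithmetic: at 250 codons, ~0.1
attempts/site total path keeps pairwise E-values many orders below 1e-30
(conserved hangs together), while ~1.6 attempts/site between subfamilies
drives amino-acid identity toward the random background so between-subfamily
E-values sit far above the cutoff (diversifying splits; diverged isolates).
The ω values span strong purifying to neutral so the dN/dS stage sees a
gradient. Subfamilies occupy contiguous leaf blocks while habitats are
assigned round-robin over leaves, so every component of every family spans
all three habitats — without this, diversifying families would have no core
clusters and an empty dN/dS table.

The default dataset is 15 families (5 per archetype, named after the
sulfate-reduction and sulfide-oxidation gene set: DsrAB, AprAB, Sat, CysNC,
CysH, CysIJ, AsrAB/C, SoxABXYZ), 3 sequences per habitat, 250 codons — 135
sequences, chosen to keep a full pipeline run under a minute on one CPU
while leaving the archetype separation unambiguous. All randomness flows
from explicit integer seeds; one root seed fans out to per-family seeds by
fixed arithmetic, and a rerun with the same seed is byte-identical in every
tabular output.

What the simulator does *not* emulate: indels (sequences are equal-length,
so the codon-pairing path through the global aligner is exercised only by
hand-made fixtures), among-site rate variation, codon-usage or GC bias,
transition/transversion asymmetry, horizontal transfer between families, and
database contamination. Passing tests therefore show the machinery is
correct under a clean neutral-ish mutation model — not that any particular
real community will separate as cleanly.

## Numerical and degenerate-input choices

* Alignment scores ≤ 0 return no hit; identity is computed over alignment
  columns (gap columns in the denominator).
* `global_topology(..., detailed=False)` skips the O(N·K) clustering and
  path statistics for large graphs where only degree/density identities are
  needed.
* Power-law fits drop nonpositive points (counted), require ≥ 3 usable
  points, and report slope 0 / r² 0 for a zero-variance response.
* Jukes-Cantor returns exactly 0 at p = 0 and +inf at p ≥ 3/4.
* The length filter is strictly greater-than (a 150-aa sequence is
  excluded at the default cutoff of 150).
* Components are reported largest-first with ties broken by smallest node
  id; all tabular outputs are written with fixed float formats so runs are
  reproducible byte-for-byte.

## Known limitations

Absolute E-values depend on the scoring constants and will not match any
specific search tool; only network-level conclusions transfer. NG86 is a
counting estimator — unweighted, no transition/transversion correction — and
is biased when divergence approaches saturation; estimates are flagged
rather than extrapolated there. The classification thresholds (isolated
fraction 0.5) are exposed configuration, not fitted quantities.
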