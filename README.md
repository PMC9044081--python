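# ssn-divergence

Sequence similarity networks (SSNs) for deciding whether microbial gene
families are **conserved** or **diversifying**, with habitat-vs-habitat
**dN/dS** on the conserved cores.

Environmental communities — e.g. the sulfur-cycling consortia of a hot
spring sampled across microbial mat, sediment and water — carry many copies
of each pathway gene (dsrAB, aprAB, sat, sox…). Whether those copies hang
together as one tight sequence cluster or scatter into fragments and
singletons is a direct, alignment-level readout of family conservation
versus diversification. This package implements that readout as a tested,
reusable pipeline:

1. **All-vs-all Smith–Waterman** (affine gaps, BLOSUM62 11/1) with
   Karlin–Altschul statistics: bitscore = (λS − ln K)/ln 2,
   E = m·n·2^(−bitscore) (λ = 0.267, K = 0.041).
2. **SSN construction** at an E-value cutoff (default 1e-30): every
   sequence is a node; isolated nodes are the highly diverged sequences.
3. **Topology**: average degree k̄ = 2K/N, density 2K/(N(N−1)), components,
   clustering coefficient, neighborhood connectivity, closeness, degree
   curves with power-law fits y = a·x^b.
4. **Classification** per family: one component and no isolated nodes ⇒
   conserved; ≥ half the nodes isolated ⇒ diverged; otherwise diversifying.
5. **dN/dS** (Nei–Gojobori counting with Jukes–Cantor correction,
   ω = dN/dS) for cross-habitat sequence pairs inside "core clusters" —
   components spanning all sampled habitats.

A codon-level family **simulator** (mutation-acceptance process on Yule
trees, acceptance odds = ω) generates conserved / diversifying / diverged
archetype families so the whole pipeline runs and is validated without any
external data. See `docs/methods.md` for the model details and conventions.

## Worked example

Run the full pipeline on the default 15-family synthetic dataset (5 families
per archetype, 9 sequences each, 250 codons):

```sh
ssn-divergence run-all --simulate-default --seed 1 --out ssn_out
```

which prints

```
records=135 filtered=135 hits=9045 edges=225
N=135 avg_degree=3.33 density=0.0249 components=65 isolated=45
AprA    conserved
AprB    conserved
AsrAB   diverged
...
SoxZ    diverged
outputs in ssn_out
```

Reading: the 135 sequences produced 9,045 positive-scoring alignments, of
which 225 pairs survive the 1e-30 cutoff. The five conserved-archetype
families each collapse to a single component (their rows in
`ssn_out/family_attributes.tsv` show `n_components=1, n_isolated=0`), the
five diversifying families split into their three subfamilies, and the five
diverged families dissolve entirely into isolated nodes — 45 of the 65
components are singletons. `ssn_out/dnds.tsv` then holds one row per
cross-habitat pair in each core cluster, e.g.

```
family  habitat_pair  id_a      id_b      ... dS        dN        omega     status
AprA    mat-sediment  AprA_000  AprA_001  ... 0.0937    0.0127    0.135     ok
```

— strong purifying selection (ω ≪ 1) on a conserved family simulated at
ω = 0.2.

The same stages are available individually (`simulate`, `align`, `network`,
`dnds`), from Python (`ssn_divergence.run_pipeline`,
`ssn_divergence.dnds_pair`, …), and on real inputs: protein FASTA + a
`id<TAB>family<TAB>habitat` metadata table, optionally coding-sequence FASTA
for dN/dS, optionally a precomputed 12-column tabular hit file (`--hits`) in
place of the internal aligner.

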