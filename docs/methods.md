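# Methods

## Model and procedure

The engine treats drug repurposing as a signature-similarity problem.
Inputs are three tables: a compound library (id, name, SMILES and/or
fingerprint bit set), a binding-site table (protein id, site id,
BSscore, native-ligand fingerprint or SMILES) and a drug-indication
mapping. Binding-site prediction itself is upstream of this package:
BSscores and site ligands are consumed as given.

1. **OBscore.** Chemical similarity between a compound and a site
   ligand is the Tanimoto coefficient of their fingerprint bit sets.
   Fingerprints are modelled as sets of non-negative pattern indices,
   not dense bit vectors; the on-disk form is a sorted comma-separated
   index list, which is backend-agnostic and diff-friendly. When both
   sets are empty the similarity is defined as 0 — two featureless
   records carry no evidence of similarity, and a conventional 1.0
   would rank all fingerprint-less compounds as identical.
2. **Interaction scores.** Per compound-protein pair, the four schemes
   (`best_ob`, `best_bs`, `best_ob+bs`, `best_obxbs`) aggregate over
   the protein's sites as described in the README. No interaction-score
   cutoff is applied anywhere: thresholding inflates the number of
   all-zero signatures, which degrade RMSD ranking (co-zero compounds
   tie at distance 0), so all-zero rows are instead counted and logged
   as a diagnostic and retained in the analysis. Dropping them would
   silently change N and the null-model arithmetic.
3. **Similarity and ranking.** Signatures are compared by
   root-*mean*-squared deviation (normalising by proteome size P); for
   a fixed P the ranking is identical to root-sum-square, but the
   mean-normalised form keeps values comparable across proteome sizes.
   Ranked lists are 1-based, self-excluded, ascending in RMSD, with
   RMSD ties broken lexicographically by compound id so every run is
   reproducible.
4. **Benchmark.** Leave-one-out per drug: "captured" means another drug
   of the same indication appears at rank ≤ k in the *left-out drug's
   own* list (the left-out drug queries, its associates are targets).
   Indications need ≥ 2 drugs to be benchmarkable; coverage is counted
   over benchmarkable indications only. Pairwise-accuracy weights are
   drug counts d_I, not pair counts d_I(d_I−1)/2. Drugs present in the
   mapping but missing from the ranked lists are a hard error rather
   than a silent shrink of d.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| `normalize_bsscore` | on | min-max rescale BSscores to [0, 1] over the whole site table |
| `cutoffs` | 10, 25, 50, 100 | top-k list cutoffs; must be < N at run time |
| control `replicates` | 100 | random matrices averaged in the uniform control |
| fingerprint backend | `morgan` | SMILES → bit-set scheme (`morgan` radius 2 / `pattern`, 2048 bits, via RDKit) |

BSscore normalization is on by default because the upstream confidence
score has no fixed documented range, and the sum/product schemes only
make sense when both factors live on comparable scales; it also makes
the scheme-ordering invariants (`best_ob+bs` ≥ `best_obxbs` entrywise)
hold. A constant score column has no min-max image; it maps to 1.0 when
positive (leaving the product scheme equal to `best_ob`) and 0.0 when
identically zero. Ties in BSscore for `best_bs` are broken by input
file order.

The fingerprint contract is "Tanimoto over a fixed substructure
fingerprint": any deterministic SMILES → bit-set backend slots in, and
precomputed bit sets bypass chemistry entirely (the default in tests,
so the core pipeline has no chemistry dependency). Bit-exact
reproduction of any particular toolkit's substructure keys is out of
scope.

## Null models

The uniform control fills the matrix with i.i.d. uniform(0, 1) scores
and runs the full pipeline per replicate, reporting Monte-Carlo means
and standard errors. Under such a matrix the non-self compounds of any
query are exchangeable, so the rank of a left-out drug's associates is
a uniform draw without replacement and the capture probability has the
hypergeometric closed form 1 − C(N−d, k)/C(N−1, k) (computed with exact
integer binomials). Expected per-indication accuracy is 100 × that
probability; expected coverage uses independence across the d left-out
drugs of an indication, which is an approximation — all d lists share
one random matrix — and is therefore validated against Monte Carlo
tolerance, not exactness.

The KS p-value uses the asymptotic series Q(λ) = 2 Σ_{j≥1} (−1)^{j−1}
e^{−2j²λ²} with λ = (√n_e + 0.12 + 0.11/√n_e)·D and n_e = nm/(n+m);
the small-sample correction keeps p usable at the modest per-cutoff
sample sizes (tens to hundreds of indications). Exact permutation
p-values are out of scope; the D statistic is cross-checked against an
independent ECDF enumeration and scipy in the tests.

## Synthetic scenarios

`generate_scenario` emulates the three input tables with a planted
chemical signal. Each indication owns a *scaffold*: a random set of
`scaffold_bits` (default 24) pattern indices in a
`fingerprint_universe` of 512. A mapped drug's base set is its
indication's scaffold; an unmapped compound's base is a random set of
the same size, so drugs and decoys have comparable fingerprint sizes.
Every universe bit is then flipped independently with
`noise_flip_prob`. At noise 0, same-indication drugs are bit-identical;
at noise 0.5 every fingerprint is a uniform random subset independent
of its base, so all compounds are exchangeable — the generator's own
exact null. A `ligand_scaffold_coverage` fraction of site ligands
borrow a random indication's scaffold (with the same noise), the rest
are random; BSscores are uniform(0, 1) or beta-distributed. Defaults
(60 compounds × 40 proteins, ten 2-4-drug indications, noise 0.1,
coverage 0.5) give a clearly super-null but desk-scale scenario; all
sizes were chosen so a full four-scheme sweep with both controls runs
in seconds.

What the generator does *not* emulate: real chemistry (valence,
tautomers, fingerprint bit correlations), overlapping indication drug
sets, heavy-tailed indication sizes, or any relation between protein
identity and ligand chemistry beyond scaffold borrowing. Passing tests
demonstrate the pipeline's arithmetic and its behaviour under a
controlled signal-to-null gradient — not performance on real compound
libraries, where fingerprint similarity is far noisier and indications
share drugs.

An `emit_smiles` mode attaches simple unbranched C/N/O-chain SMILES to
generated compounds purely to integration-test the SMILES loading path;
these molecules are valid but chemically arbitrary, and the planted
bit-set fingerprints remain authoritative.

## Numerical choices and degenerate inputs

* All-zero signatures: retained, counted, logged (see above).
* Proteins with zero predicted sites: score 0 under every scheme.
* Matrix storage is dense; at the intended scales (≤ a few thousand
  compounds) RMSD over dense rows is trivially verifiable and fast.
* Matrix files round-trip bitwise: floats are written repr-faithfully
  and parsed with round-trip precision.
* `ranked_list` requires ≥ 2 compounds; `benchmark_all` requires ≥ 1
  benchmarkable indication; cutoff ≥ N fails before any computation.
* Seeds: every stochastic routine takes an explicit seed;
  replicate-level seeds are spawned from one generator so runs are
  reproducible end to end from the manifest.

## Known limitations

* The hypergeometric coverage expectation ignores within-indication
  list dependence (documented above).
* The benchmark treats indication drug sets as disjoint evidence; a
  drug approved for many indications contributes to each
  independently.
* `best_bs` depends on the BSscore ordering only through the argmax, so
  it is insensitive to normalization but sensitive to ties; the
  file-order tie-break is deterministic but arbitrary.
* Scheme comparisons on synthetic data need not transfer to real
  libraries: with strongly planted scaffolds all four schemes saturate,
  and differences emerge only at intermediate noise.
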