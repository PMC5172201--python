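# Methods

## Model

The package treats disease comorbidity as a two-channel signal: direct
genetic overlap between two diseases' associated gene sets (NG), and
indirect network-level association of those sets (XD), validated against
clinical co-occurrence (RR, PHI).

**Propagation.** The gene network is an undirected weighted simple graph.
Self-loops are removed on load and duplicate edges merge keeping the maximum
weight (the convention used when confidence channels are merged in
STRING-style resources). The walk iterates `s ← (1−p)·W·s + p·s₀` where `W`
column-normalizes the adjacency by degree (by weighted degree with
`weighted=True`; the default is unweighted because it is not established
that confidence scores should serve as walk weights). `s₀` is uniform over
the seed genes present in the network. The raw formulation seeds with 1s;
normalizing to sum 1 rescales all scores by a constant, which cannot change
bin membership (bins depend only on relative position in `[m, M]`), and buys
the conservation invariant `Σs = 1`, used as a numerical check. Genes with
no neighbours have their transition column replaced by the restart
distribution (the standard teleport fix), which keeps the iteration
stochastic and is implemented implicitly by routing dangling mass back to
`s₀`. Convergence: L1 change below `tol = 1e-10`, capped at 1000 iterations
(flagged in the result). A dense linear solve of `(I − (1−p)W)s = p·s₀`
(`rwr_exact`) serves as an independent cross-check in tests, not as the
production path.

**Restart probability.** `p = 0.9` by default, interpreted as the
probability mass returned to the seeds each step — the convention in which
larger `p` keeps the walk nearer the seeds.

**XD score.** Bins are equal-width over `[m, M]`: gene with score `s` lands
in bin `min(n, floor(n·(M−s)/(M−m)) + 1)`, so the maximum score is in bin 1
and the minimum in bin `n` (`n = 10` by default). Ties share a bin by value.
The directed score is the rank-weighted difference `Σᵢ (P_ic − P_ia)/i`:
the unweighted sum is identically zero, while the `1/i` weighting makes the
score positive exactly when target genes concentrate in high-score bins and
negative when they concentrate low — matching the intended reading that a
negative score means below-average network association. The weighting is a
pluggable strategy (`weights=`), so alternatives such as geometric decay can
be swapped without touching callers. The final pair score is the minimum of
the two directions (each disease seeding once), a conservative symmetric
choice. One walk is run per disease, cached, not one per pair.

Degenerate cases: if all scores are equal the profile collapses to a single
flagged bin and XD is 0 with a warning. A gene set with no network overlap
makes the pair *unscorable* — a distinct state, never coerced to XD = 0.
Target genes that are also seeds stay in the target set (they occupy the top
bin); excluding them (`exclude_overlap=True`) is supported but off by
default, since shared genes are precisely the direct channel the combined
classification is meant to capture.

A structural note, established by brute-force computation during
development: with `p = 0.9` a non-seed gene's score is bounded near
`(1−p)·M`, so under equal-width bins a target set completely disjoint from
the seeds essentially cannot reach the top bins, and positive XD in both
directions arises mainly when the sets overlap or funnel onto one another.
This is consistent with positive-XD pairs being a small minority of all
pairs and overlapping heavily with gene-sharing pairs.

**Classification.** Pairs are labelled by sign of XD (`> 0`) and presence of
shared genes (`NG ≥ 1`): `+XDand+NG`, `+NGnot+XD`, `+XDnot+NG`,
`not+XDnot+NG`; marginal filters `+XD`, `+NG`, and `ALL` are used for
correlation tables. NG is counted on the full association sets, not the
network-restricted ones: gene sharing is a fact about the disease databases,
independent of network coverage.

**Clinical statistics.** For diseases i, j: `C_ij` patients with both, `I_i`,
`I_j` with each, `N` total. `RR = C_ij·N/(I_i·I_j)`;
`PHI = (C_ij·N − I_i·I_j)/√(I_i·I_j·(N−I_i)·(N−I_j))`, identical to the
Pearson correlation of the binary indicators (asserted to 1e-12 in tests).
Undefined entries (absent disease for RR; universal or absent disease for
PHI) are flagged, excluded from correlations, and counted. All loaded
patients contribute to `N`, including patients with no mapped diagnosis —
the records format preserves them so prevalences and RR stay unbiased.

**Permutation significance.** The p-value for an observed Pearson
correlation is the fraction of `n_perm` independent reshufflings of one
variable whose correlation is *strictly greater* than the observed one:
one-sided, no add-one smoothing, so the smallest resolvable p is `1/n_perm`
(reported in the output). Shuffling one list is equivalent in distribution
to shuffling both. The default `n_perm` is 2,000,000; tests and the
acceptance script use 2,000–100,000, which bounds p-resolution but not
correctness.

**Disease network and null.** Edges are the `+XDand+NG` pairs, weighted by
XD; isolated diseases are excluded. Per-category mean degree counts links to
any category. Normalized link scores divide observed counts by `|A|·|B|`
between categories and `C(|A|,2)` within. "Edge shuffling" is
degree-preserving double-edge swapping (default 10·|E| attempted swaps per
replicate); per category pair, `p = #(null count ≥ observed)/n_shuffles`,
floored at `1/n_shuffles`, with the significant-entry fractions summarized
at α = 0.05. Graphs admitting no valid swap (stars, etc.) fall back to a
category-label permutation null with a warning. The default replicate count
is 1,000,000; tests use 2,000–10,000, where the planted-signal and
calibration properties are already decisive.

**Enrichment.** Hypergeometric upper-tail p per (disease, term) over the
universe of annotated genes (standard enrichment practice: un-annotated
genes carry no information for the test), raw cutoff 0.05 with no
multiple-testing correction by default (a Benjamini–Hochberg option exists).
Annotations are used flat, as given, with no ontology-hierarchy propagation.
Shared-mechanism reporting gives both `|shared|/min(|a|,|b|)` (headline) and
Jaccard, since the denominator convention is ambiguous in informal usage;
the Fisher's exact test for over-sharing is one-sided on the 2×2 table over
all annotation terms.

## Synthetic study conditions

The generators emulate the shape of the real inputs, with ground truth
recorded for recovery testing. Defaults (the standard test condition):

| parameter | default | rationale |
|---|---|---|
| genes | 100, 4 planted modules | smallest size at which 10 score bins resolve module structure |
| within/between edge prob. | 0.5 / 0.01 | modularity ≈ 0.6, a strongly modular functional network |
| diseases | 12, 8–15 genes each | enough pairs (66) for category tables at desk scale |
| planted pairs | 2, same module, ≥3 shared genes | network-proximal and gene-sharing, i.e. true `+XDand+NG` members |
| patients | 50,000 | relative-risk sampling error ≪ the planted effect |
| prevalences | log-uniform on [0.01, 0.1] | heavy-tailed, mimicking clinical prevalence; makes RR and PHI diverge, which is why both are kept |
| comorbidity lift | 5 | planted joint probability = 5 × product of marginals (capped at the smaller marginal, with warning), so the target RR is analytic |
| annotation terms | 30, module-aligned | each module spawns a term covering ~80% of it, so planted pairs share enriched mechanisms |

Planted comorbidity is injected at the joint-probability level rather than
through shared latent causes, precisely so the target RR is known in closed
form. What the generator does *not* emulate: ICD-code hierarchy, age/sex
structure, coding noise, correlated background comorbidity, and the
scale-free degree structure of real interactomes (available via the
Barabási–Albert model but not the default). Passing recovery tests therefore
demonstrate internal correctness and sensitivity of the method under clean
planted signal, not performance on real claims data.

## Numerical and design choices

- Deterministic everything: loaders sort genes lexicographically, pair
  tables are ordered, all randomness flows from one root seed split per
  stage via `SeedSequence`; pipeline reruns are byte-identical.
- Float weights round-trip through TSV via `repr` (shortest exact form).
- Confidence filtering of input networks (`min_weight`) is opt-in, defaulting
  to no filter.
- Patient-records TSV accepts a blank disease field as "enrolled, no mapped
  diagnosis" so the cohort size survives write/load; blank patient ids are
  errors.
- The permutation p and the shuffle-null p intentionally differ in tie
  handling (strict `>` with no floor vs `≥` with floor): the former follows
  the verbatim definition of the correlation test; the latter is an
  enrichment count where the observed network itself is a valid draw.
- Problem sizes in tests and the acceptance script (graphs ≤ 200 nodes,
  2,000–100,000 permutations, 2,000–10,000 shuffles, 10–20 seeded
  replicates) are the package's chosen desk-scale conditions; defaults in
  the API remain the full-scale values.

## Known limitations

- Equal-width binning plus a high restart probability makes `+XDnot+NG`
  rare on small synthetic networks (see the structural note above); on
  large real networks with hub-rich topology the category populates.
- The edge-shuffle null conditions on the degree sequence only; category
  sizes are not rebalanced.
- No prevalence correction, age/sex stratification, or multiple-testing
  correction across correlation-table cells — matching the plain
  definitions of the statistics reported.
- GO terms are tested flat; ancestor propagation would change both
  enrichment and sharing statistics.
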