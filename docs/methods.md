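# Methods

This document records the mathematical definitions and numerical choices
implemented in `ddibalance`, in enough detail to reimplement the package.

## 1. Signed networks and triad balance

A signed DDI network on `m` drugs is a symmetric matrix
`A ∈ {−1, 0, +1}^{m×m}` with zero diagonal: `+1` encodes an enhancive
interaction, `−1` a degressive one, `0` no known interaction. The
enhancive/degressive split is elementwise:

```
A⁺ = (|A| + A) / 2        A⁻ = (|A| − A) / 2
```

so `A = A⁺ − A⁻`, both parts nonnegative with disjoint support. `L⁺ = D⁺ −
A⁺` is the combinatorial Laplacian of the enhancive subnetwork (`D⁺` the
diagonal degree matrix of `A⁺`); it is positive semidefinite with zero row
sums.

**Triad census.** Every unordered node triple whose three pairwise edges
are all nonzero is a triangle, classified by its multiset of signs: PPP,
NNP (two negative, one positive), NNN, PPN (two positive, one negative).
Under weak structural balance PPP and NNP are strongly balanced, NNN weakly
balanced, and PPN unbalanced. Counts are computed by trace identities on
`P = A⁺`, `N = A⁻`:

```
#PPP = tr(P³)/6     #NNN = tr(N³)/6
#PPN = Σ(P² ∘ N)/2  #NNP = Σ(N² ∘ P)/2
```

(`∘` elementwise), each verified in the tests against brute-force triple
enumeration.

**Sign-shuffle null.** Shuffling the signs uniformly over the fixed edge
support makes each triangle's sign pattern an exchangeable draw of three
signs without replacement from the pool of `E⁺` positive and `E⁻` negative
signs. The expected fraction of each class is therefore hypergeometric and
*independent of the topology*:

```
P(PPP) = C(E⁺,3)/C(E,3),  P(PPN) = C(E⁺,2)·C(E⁻,1)/C(E,3),  etc.
```

with `E = E⁺ + E⁻`. The package provides both the closed form
(`expected_shuffled_triad_fractions`) and actual shuffling
(`shuffle_signs`), and the tests confirm they agree.

## 2. Balance-regularized semi-NMF (BRSNMF)

### Objective

```
J(W, H) = ‖A − WHᵀ‖²_F + α · Sr − β · Gr,    H ≥ 0
Sr = tr(H 1_k Hᵀ) = Σ_i (Σ_j h_ij)²
Gr = tr(Hᵀ (σI − η (A⁻ + L⁺)) H)
```

`W ∈ R^{m×k}` holds real community centroids, `H ∈ R₊^{m×k}` soft
indicators. `Sr` penalizes multi-community membership. `Gr` is the balance
reward: the quadratic form `Hᵀ(A⁻ + L⁺)H` charges degressive edges placed
inside a community and enhancive edges cut between communities, while `σI`
rewards indicator mass. Defaults `α = β = η = σ = 1`.

### Updates

* **Centroids** (exact least squares): `W = AH (HᵀH)⁻¹`, with a small
  ridge `λ = 10⁻⁸ · tr(HᵀH)/k` added to the Gram matrix so collapsed
  indicators stay solvable; an unsolvable or non-finite system raises a
  singular-indicator error.
* **Indicators** (multiplicative KKT step): `H ← H ∘ √(N / (D + ε))` with

  ```
  N = (AW)₊ + H(WᵀW)₋ + βη·A⁺H + βσ·H
  D = (AW)₋ + H(WᵀW)₊ + α·H1_k + βη·(A⁻H + D⁺H)
  ```

  where `X₊`/`X₋` are elementwise positive/negative parts and
  `ε = 10⁻¹²` guards empty denominators. `N − D = −∇_H J / 2`, so fixed
  points satisfy the KKT conditions; the split keeps both sides
  nonnegative, preserves `H ≥ 0`, keeps zero entries zero, and is
  empirically non-increasing in `J` (tested over hundreds of random
  instances at relative tolerance 1e−8).

  A note on the split: the gradient can also be split at the *product*
  level (positive/negative parts of `H(WᵀW)` and of `L⁺H` as whole
  matrices). That variant has the same fixed points but is **not**
  monotone — in our experiments it increased the objective by many orders
  of magnitude — so this package uses the matrix-level split above, the
  standard form in the semi-NMF literature.

* **Initialization** (`init="kmeans"`, the default): k-means on the rows
  of `A` (10 restarts, seeded), `H₀` = one-hot membership + 0.2, `W₀` from
  the centroid update. `init="random"` draws `H₀ ~ U(0,1)`.

* **Convergence:** stop when the relative objective change drops below
  `tol` (default 1e−6) or after `max_iter` (default 500) iterations; the
  full objective trace is returned.

With `α = β = 0` both updates reduce algebraically to plain Semi-NMF, and
the implementation shares the code path so `brsnmf(α=β=0)` equals
`semi_nmf` bit-for-bit.

**Hard partition.** `assign_communities` takes row-wise argmax of `H`
(ties to the lowest index), errors on all-zero rows, and compacts empty
communities with a warning.

## 3. Balance metrics

**Community balance index (CBI).** For partition `{C_1..C_k}` with sizes
`n_c`, let `T_c` be the triangles entirely inside `C_c` and `U_c ⊆ T_c`
the unbalanced (PPN) ones:

```
CBI = Σ_c n_c · (1 − |U_c|/|T_c|)  /  Σ_c n_c      ∈ [0, 1]
```

A community with no internal triangle contributes factor 1 (it contains no
violation; `0/0 := 1` by design). Reported as a fraction and as a percent.

**Within/between contrasts.** With `e⁺`, `e⁻` the enhancive/degressive
edge counts in a community (or between a pair of communities) and `n(n−1)/2`
(resp. `n_a n_b`) the possible pairs, the rate ratios are
`Re = (e⁺ + ½)/pairs`, `Rd = (e⁻ + ½)/pairs` (pseudo-count ½ in the
numerators keeps logs finite), and

```
Δ = ln Re − ln Rd        SRw = Re_raw + Rd_raw        DRw = Re_raw − Rd_raw
```

(`SRw`/`DRw` use raw ratios without pseudo-counts, so `SRw ∈ [0,1]`,
`|DRw| ≤ SRw`). `Δw > 0` marks an enhancive (strongly balanced) community,
`Δw < 0` a degressive (weakly balanced) one; `Δb < 0` between communities
matches weak balance. Communities with fewer than 2 members are flagged and
reported as NaN (JSON `null`).

## 4. Cold-start prediction

1. **Train** on the known-drug network: `A ≈ WHᵀ` by BRSNMF, then a PLS2
   regression `H ≈ FB` from the `m×p` binary feature matrix. The PLS is
   NIPALS-style on the **uncentered** matrices — each component takes the
   dominant singular pair of `XᵀY` and deflates both blocks — so the map is
   strictly linear and a zero feature row maps to a zero latent row (a
   featureless drug gets no prediction rather than a population-mean
   prediction). Components: `min(k, p, m−1)`. On centered data the
   implementation agrees with scikit-learn's `PLSRegression` (tested).
2. **Predict**: `Ax = (Fx B) Wᵀ` for query features `Fx`; sign of the
   score is the predicted polarity, magnitude the confidence.
3. **Default latent dimension**: `k = round(rank(A)/10)` (numerical rank
   at tolerance 1e−8, floor 1).

**Evaluation (rank-based only).**

* *top-n / bottom-n accuracy*: fraction of truly enhancive pairs among the
  `n` largest signed scores, and truly degressive among the `n` smallest,
  pooled over all query–target pairs with deterministic label tie-breaks.
* *AUROC / AUPR*: detection of any interaction, `|label|` against
  `|score|` (scikit-learn implementations; NaN when truth is one-class).
* *MPR*: for each true interaction, its 0-based percentile position in its
  query row sorted by `|score|` descending, averaged (0 is best).

**Cross-validation** is at the *drug* level (LOOCV or seeded n-fold): a
fold removes whole drugs and all their interactions from training, then
predicts those drugs from features alone — the honest cold-start protocol;
an assertion verifies no held-out drug remains in any training network.

## 5. Synthetic benchmarks

`PlantedSpec` draws planted-partition signed networks: within-community
pairs carry an edge with probability `within_edge_prob` and the
community's planted sign (+1, or −1 for a weakly balanced block); between
pairs with probability `between_edge_prob` and sign −1 except a
`between_positive_rate` fraction; finally a `flip_rate` fraction of signs
is flipped. Under flips `q`, a within triangle is PPN exactly when one of
its three edges flipped, so the true partition's expected CBI is
`1 − 3q(1−q)²` — a closed form the tests check the generator against.

`community_linked_features` gives each community a disjoint block of
`⌊p/k⌋` marker features (1 with probability `signal`; all other features 1
with probability `noise`); `signal = noise` erases community information.

`coldstart_benchmark` is the standard 120-drug benchmark used in the tests
and examples: 3 communities of 40, within/between edge probabilities
0.9/0.1, 5% flips, 5% positive between-edges, 60 features at signal 0.9 /
noise 0.1 — sized so a desk-scale laptop run finishes in seconds while
leaving enough noise that recovery is non-trivial.

`toy_signed_network` is a hand-built 13-drug, 4-community illustration whose
triad census (PPP 4, NNP 0, NNN 1, PPN 1) is dominated by balanced
triangles, with its one unbalanced triangle spanning two communities.

## 6. Known limitations

* **The balance reward can disfavor weakly balanced blocks.** `Gr` charges
  `Hᵀ A⁻ H`, i.e. *any* degressive edge inside a community — including the
  intentional ones of an all-degressive (weakly balanced) community. On
  small dense planted instances containing such a block, the regularized
  objective's own optimum sometimes moves a node out of the planted
  partition, and plain Semi-NMF attains fractionally higher CBI (measured
  0.8321 vs 0.8304 over 40 instances). The corresponding acceptance test
  is left failing rather than weakened; the regularizer's advantages
  (balanced community sizes, balance-aware cuts) belong to large sparse
  regimes where unregularized factorizations degenerate.
* **CBI rewards fragmentation.** Triadless communities count as fully
  balanced, so CBI comparisons are only meaningful between partitions of
  similar granularity.
* **Multiplicative updates converge to local optima.** Results depend on
  the seeded initialization; the k-means recipe is reliable on
  block-structured networks but small, loosely connected networks can
  still end in poor local optima. The objective trace is returned so runs
  can be compared.
* **PLS without centering** trades a little accuracy for strict linearity;
  features must be informative in their raw binary coding.
* **No score calibration.** Predicted scores order pairs; they are not
  probabilities and have no fixed interaction threshold.
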