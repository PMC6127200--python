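# Methods

## The QACO predictor

QACO treats link prediction as a biased exploration problem on the completion
G′ of the observed (training) network: every node pair is walkable, and the
amount of pheromone a pair accumulates over repeated ant walks — together
with a static similarity term — is read out as its likelihood score.

State per run, for a training graph with n nodes and m ants:

* **Link pheromone τ** (n×n, symmetric, zero diagonal): initialised to δ on
  every pair. Each iteration it decays to ρ·τ, then every realised step
  (vᵢ → vⱼ) of ant k deposits Q_k·(1 − β_{j,k}²), applied symmetrically.
  Q_k = C·(mean training degree of the nodes on ant k's path) rewards paths
  through well-connected regions; the (1 − β²) damping shrinks deposits onto
  nodes that have already been visited often, counteracting the
  rich-get-richer feedback that traps plain ant systems in local optima.
* **Visibility η** (n×n, static): the quasi-local similarity
  η_ij = Σ_{z∈Γ(i)∩Γ(j)} k(z)^−ι + ω·Σ (k(x)·k(y))^−ι, the second sum over
  ordered intermediate pairs (x, y) of simple length-3 paths i–x–y–j with
  x, y ∉ {i, j} and x ≠ y. It is computed densely for all pairs (adjacent
  included — ants may walk existing links) by matrix algebra: the raw triple
  product (A·D_w)·A·(D_w·A) counts all x, y walks; the x = j and y = i
  violations both carry a factor A_ij and are removed by inclusion–exclusion,
  and x = y vanishes because A has a zero diagonal. The unit suite verifies
  this against an exhaustive path-enumeration oracle on all connected labelled
  graphs with ≤ 5 nodes and thousands of random 6–7-node graphs, to 1e-12.
* **Quantum register** (n×m qubit pairs): node j holds one qubit (α, β) per
  ant, all initialised to (1/√2, 1/√2), so every node starts with intensity
  μ = 1/α² = 2. When ant k's path visits node j, the k-th qubit of j is
  rotated once by the gate
  (α, β) → (cos θ·α − sin θ·β, sin θ·α + cos θ·β), θ = Δθ·sign(α·β).
  The sign rule makes the basis states fixed points and drives mixed states
  monotonically toward |1⟩, raising μ and making visited nodes more
  attractive. The gate is orthogonal, so α² + β² = 1 is preserved to
  round-off regardless of iteration count.

A walk step from i samples j among unvisited nodes with probability
∝ τ_ij^λ · η_ij^κ · μ_j^ν (0⁰ := 1). Walks are tabu (no node revisited) and
synchronous: all m ants read the τ, η and register state frozen at the start
of the iteration; τ and the register are updated once per iteration. Ants are
placed by shuffling the node order and assigning the m ants to the first m
nodes. After N_c iterations the score of a pair is τ_ij + ε·η_ij, ranked over
pairs non-adjacent in the training graph.

### Parameters

| symbol | name | default | meaning |
|---|---|---|---|
| δ | `delta` | 1 | initial pheromone on every pair |
| λ | `lam` | 1 | pheromone exponent in the transition weight |
| κ | `kappa` | 2 | visibility exponent |
| ν | `nu` | 1 | node-intensity exponent |
| ρ | `rho` | 0.9 | pheromone persistence per iteration, ∈ [0, 1) |
| ε | `eps` | 0.2 | weight of η in the final score |
| ω | `omega` | 0.01 | weight of the length-3-path visibility term |
| ι | `iota` | 1 | degree exponent in η: 0 = raw counts, 1 = resource-allocation weighting; pick per topology |
| Δθ | `dtheta` | 0.05π | rotation magnitude; recommended range [0.01π, 0.08π], validated |
| C | `C` | 1 | fitness gain; scales deposits linearly, so it is a free gain |
| m | `n_ants` | 50 | colony size (must not exceed n) |
| N_c | `n_iter` | 20 | iterations |
| — | `path_len` | n | steps per ant per iteration, capped at n by the tabu rule |

The (δ, λ, κ, ν, ρ, ε, ω) defaults are the published experimental setting for
this family of predictors; Δθ is fixed at the midpoint of its recommended
range (an adaptive Δθ schedule is possible but out of scope). `n_ants` and
`n_iter` default to the scaled study conditions used throughout the test
suite (N = 100 networks); both scale the compute budget, and larger networks
may warrant more iterations.

### Numerical choices

* μ = 1/max(α², 1e-6): the floor caps node intensity at 10⁶ as a qubit
  approaches |1⟩, keeping transition weights finite.
* If every candidate weight is zero (possible when κ > 0 and η vanishes
  toward all unvisited nodes), the step falls back to the uniform
  distribution over candidates; the 0/0 of the normalised rule is undefined
  and uniformity preserves ergodicity.
* Ranking ties are broken deterministically: score descending, then the
  label-sorted node pair ascending lexicographically. This makes every
  ranking, report and CLI output reproducible byte-for-byte from the seed.
  The flip side is that a *constant* score column is not an unbiased null —
  the lexicographic order correlates with edge placement in most graphs — so
  null calibrations use exchangeable random scores instead (see below).
* One seeded generator (numpy PCG64) drives ant placement and every walk;
  per-split and per-round seeds are derived from the top-level seed.
* τ, η and score matrices are dense n×n floats; memory is the practical
  bound (n ≈ 10,000 on a desktop). Sparse η would be an optimisation, not a
  semantic change.
* Complexity is O(n⟨k⟩³) for η plus O(N_c·m·n²) for the walks — quadratic in
  n at fixed colony size, which the suite checks as a loose timing
  monotonicity only.

## Baselines

* **CN**: |Γ(x) ∩ Γ(y)|, computed as A².
* **CH**: Σ_{z∈Γ(x)∩Γ(y)} |γ(z)|/|Γ(z)|. Implemented by direct set
  enumeration over pairs with at least one common neighbour.
* **SPM**: defaults perturb_fraction = 0.1, n_avg = 10 (the literature's
  convention; the method's source gives no universal setting). Eigenvalue
  corrections are applied per eigenvector exactly as computed by `eigh`; no
  degenerate-subspace rotation is attempted, and a near-degenerate spectrum
  (gap < 1e-8) triggers a logged warning. With an empty perturbation set the
  reconstruction equals A to eigensolver round-off — the identity limit the
  tests pin at 1e-8. First-order corrections on non-degenerate eigenvalues
  are cross-checked against finite differences of the eigenvalues.

## Synthetic generators

**Watts–Strogatz**: ring lattice with m_half neighbours per side
(|E| = N·m_half), each edge independently rewired with probability β to a
random non-duplicate, non-self endpoint (delegated to networkx, whose
construction is exactly this). β = 0 gives the 2·m_half-regular lattice; the
expected number of rewired edges is β·|E|.

**nPSO-style**: popularity-similarity growth in the hyperbolic disk. Node t
(1-based) appears at radius r_t = 2·ln t; at that moment every earlier node s
sits at b·r_s + (1 − b)·r_t with fading exponent b = 1/(γ − 1), which yields
a degree power law with exponent γ. Angles are drawn from an equal-weight
mixture of von Mises components with means equally spaced on [0, 2π) and
standard deviation (2π/n_comm)/6 by default — the component of each draw is
the node's ground-truth community, returned alongside coordinates. Each new
node connects to exactly m_half existing nodes sampled without replacement
with weights exp(−(d − d_min)/(2T)) in hyperbolic distance d (Gumbel-top-k
sampling); as T → 0 this selects the m_half hyperbolically closest nodes.
The first m_half arrivals connect to all prior nodes, so
|E| = N·m_half − m_half(m_half + 1)/2.

What the generators emulate — and what they do not: the WS family probes
predictors on locally clustered, nearly regular topologies; the nPSO-style
family adds heavy-tailed degrees, planted communities and tunable clustering
(higher at low T). Neither reproduces degree correlations, weighted or
temporal structure of specific real networks, so a predictor's performance
here demonstrates recovery of *planted* topology classes, not performance on
any particular empirical network. The hyperbolic generator follows the
standard growth rule but is not a line-for-line port of any published
implementation; its attachment uses the softmax-style weights above rather
than a Fermi connection probability with a fitted cutoff radius.

## Evaluation protocols

* **Splits**: edges are partitioned uniformly at random;
  |E^T| = round(fraction·|E|) with half-up rounding. The training graph keeps
  all nodes, so probe edges with isolated endpoints remain scoreable. No
  connectivity repair is attempted — the protocol does not require it.
* **Precision**: with L predictions, the fraction of the top-L candidates
  that are probe links. Repeated-split evaluation uses L = |E^P| per split,
  matching the time-evolving protocol's top-r convention. Under an
  exchangeable null the expectation is |E^P|/#candidates (hypergeometric),
  which the suite verifies over 10,000 splits with random-score ranking.
* **Precision-ranking**: predictors ranked per network (rank 1 best, ties at
  the midpoint), averaged over networks.
* **Permutation tests**: paired sign-flip on the two rank columns
  (networks are the pairing blocks), statistic |mean difference|, two-sided
  p with add-one correction; all pairwise p-values adjusted by
  Benjamini–Hochberg.
* **Time-evolving protocol**: for snapshots i < j, candidates are the pairs
  non-adjacent at time i with both endpoints still present at time j; with r
  the number of candidates that are edges at time j, the cell precision is
  |top-r ∩ edges(j)|/r. Cells with r = 0 are skipped and the mean covers
  defined cells only.

## Problem sizes used by the test and acceptance runs

The repeated-split benchmark runs on WS networks with N = 100, m_half = 10,
β = 0.01 over 20 splits at 90/10, with 50 ants and 20 iterations; the
hyperbolic clustering comparison uses N = 1000 with 10 networks per
temperature. These sizes exercise every code path at full fidelity while
keeping a complete run in the tens of seconds; all of them scale up by
changing the corresponding parameters.

## Known limitations

* Undirected, unweighted, single-layer networks only.
* Dense matrices bound n; no sparse or out-of-core path.
* Ant walks are sequential; the synchronous-iteration semantics would admit
  parallel ants, but no parallel execution is implemented.
* The fitness family is fixed to mean path degree; alternative fitnesses are
  out of scope.
* SPM's per-eigenvector correction is the plain first-order reading; on
  graphs with highly degenerate spectra (e.g. many disconnected isomorphic
  components) the correction basis is arbitrary within each eigenspace.
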