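# Methods

## Model

The GALT circuitry is a fixed directed graph `g` with `V` labelled vertices
(one antigen source, cellular and molecular components) and binary
adjacency `a_ij`. Stimulation diffuses as a discrete-time random walk with
injection: per iteration every walker steps to a uniform out-neighbour of
its vertex, then one walker spawns at the source, then occupancy is
recorded. The ensemble size is therefore exactly `N(t) = t`; no walker is
ever destroyed. The flux vector `f_i(t) = σ_i(t)/N(t)` is the model's
activation measure: it is a probability distribution over components at
every recorded time.

The single-step law is the row-stochastic matrix `T`, `t_ij = a_ij /
k_i^out`. Flux vectors are **row** vectors updated as `f ← f T`, so the
rows of `T^∞` (when it exists) are the asymptotic flux. Sinks (out-degree
0, possible only in knockout graphs) keep their walkers: analytically a
self-loop `t_ii = 1` (`sink_policy="self_loop"`, the default; `"reject"`
refuses to build the matrix).

### Asymptotic flux

Because one walker of every age `0..t-1` is present, the exact expected
flux is the Cesàro average `(1/t) Σ_{k<t} e_src T^k`. Three consistent
routes are implemented:

1. `stationary_flux`: the unique `π = πT` when the chain has a single
   recurrent class (found by strongly-connected-component analysis of the
   support graph). Computed from the dominant left eigenvector, falling
   back to the balance equations with a normalisation row (least squares)
   when the eigensolver cannot isolate the unit eigenvalue — which is
   exactly the near-periodic case, e.g. the plain star whose subchain
   spectrum is {1, −1, 0}. Transient vertices (the source, when nothing
   feeds it) carry mass 0.
2. `cesaro_limit`: the exact `t → ∞` limit for *any* chain — absorption
   probabilities from the source into each recurrent class (fundamental
   matrix `(I−Q)^{-1}R`) times each class's internal stationary vector.
   The knockout screen's "analytic" route uses `stationary_flux` and falls
   back to `cesaro_limit` when a knockout splits the chain into several
   recurrent classes; the two agree exactly in the single-class case.
3. `expected_flux_cesaro`: the finite-`t` average itself, evaluated by a
   binary-doubling recursion on the pair `(T^m, Σ_{k<m} T^k)`
   (`S_{2m} = S_m + T^m S_m`), i.e. `O(log t)` dense matrix products.
   This is what makes the exact route at the study scale `t = 10^4`
   (healthy graph plus all 32 knockouts) run in well under a second,
   versus hours for the equivalent walker simulation.

Perron–Frobenius applicability (`check_perron_frobenius`) is reported as:
exactly one eigenvalue of magnitude 1 (tolerance `1e-9`) *and* a single
recurrent class. Periodic chains (the 3-cycle: cube roots of unity) and
multi-class chains fail it; the Cesàro routes still apply there.

### Simulation

`run_realization` propagates occupancy counts: per iteration one batched
multinomial draw per vertex (`rng.multinomial(occupancy, T)`),
distributionally identical to moving walkers one by one; the literal
walker-by-walker loop (`naive_realization`, `O(t²)`) is retained and
cross-checked against it at small `t`. Realization `r` of a run seeded `s`
uses `default_rng(SeedSequence((s, r)))`, so results are bitwise
reproducible and independent of execution order. `mean_flux` averages `L`
realizations and attaches the per-vertex standard error of the mean.
Recording after the spawn means the source always holds the newest walker:
`f_src = 1/t` exactly, a deterministic `O(1/t)` transient that vanishes in
the analytic limit.

### Knockout statistic

Knockouts remove one non-source vertex (identity across graphs is by
label; the removed label carries flux 0 on the healthy index). The
per-vertex relative error scales `|Δf_i|` by the larger of the two
densities, so `p_i ∈ [0, 1]` always; `Δf_i = 0` contributes 0. The mean
relative deviation divides by the healthy `V` (33 for the packaged
network). Defaults, both exposed as flags: the removed vertex is counted
(it contributes `p = 1` whenever it carried flux), the source is forced to
`p = 0` (its occupancy is an artefact of the injection, not a biological
activation). The cross-method discrepancy (`compare_methods`) is the mean
over knockouts of `|P̄_a − P̄_s| / max(P̄_a, P̄_s)`, in percent — the same
larger-denominator convention as `p_i`.

## The packaged network

33 vertices (1 antigen, 23 cellular, 9 molecular), 84 edges. The published
diagram is graphical only, so the edge list is hand-transcribed from the
narrative of antigen entry (IgG/FcRn, IgA/M cells, tight junctions,
transcellular and MHC II exosome routes, goblet-cell passages, CX3CR1+
phagocytes), CD103+ DC migration and presentation, regulatory T-cell
induction (TGF-β, RA, IL-2), gut homing (α4β7/MadCAM-1, CCR9/CCL25) and
the IL-27/Tr1/IL-10 suppressor loop. Two transcription choices matter and
are recorded in the manifest:

* every non-source component has out-degree ≥ 2 (each edge narratively
  supported). This reflects the redundancy of the GALT circuitry and has a
  structural consequence: no single knockout can create an absorbing sink.
  In a sparser transcription a knockout that strands a downstream component
  with no exits turns it into an absorber that soaks up *all* asymptotic
  flux, driving nearly every knockout's `P̄` toward 1 — qualitatively
  unlike the moderate impact spectrum the screen is meant to resolve;
* the narrative's feedback interactions (TGF-β on the epithelium and
  barrier, IL-10 on macrophages, IFN-λ on the epithelium, CCL25 attracting
  CCR9⁺ pDCs) are included, making the non-source subgraph strongly
  connected and aperiodic — so the chain is ergodic on it, every component
  carries positive asymptotic flux, and the Perron–Frobenius route applies
  to the healthy graph.

With this transcription the screen's headline result is robust across all
three routes: the CD103+ knockout is ranked first (analytic `P̄ = 0.511`),
consistent with its biology as the conduit between antigen sampling and
T-cell priming; TGF-β, IL-10, iTregFoxP3+ and RA follow. The spectrum of
the healthy matrix has `|λ₁| = 1`, `|λ₂| ≈ 0.671`. Exact per-component
values depend on the transcription and are therefore reported by
`scripts/acceptance.py` rather than promised.

## Synthetic generator

`generate_network` draws a directed Erdős–Rényi graph (default edge
probability 0.3, no spontaneous self-loops) over `V` vertices with vertex 1
as source, then *repairs* rather than rejects: an out-edge for every sink,
a source edge to every unreachable vertex, a self-loop on a periodic
terminal class when aperiodicity is requested. Repairs are logged in the
network's provenance. Generation is deterministic per seed. The generator
emulates the structural assumptions of the study network (single source,
no isolated vertices, directedness, reachability) but *not* its biology:
no hub structure, no functional modules, no degree-distribution targeting
(the study network is small and not scale-free, so there is nothing to
emulate there). Passing tests on generated graphs therefore validate the
walk/screen machinery, not any immunological claim.

## Numerical choices and problem sizes

* Eigenvalue-multiplicity tolerance `1e-9`; stationary fixed-point residual
  checked at `1e-8` before the eigenvector is accepted.
* Flux vectors sum to 1 within `1e-12` on every route.
* Default desk-scale simulation `t = 10³, L = 10²`; the study scale
  `t = L = 10⁴` is supported (`--paper-scale`) but the exact-expectation
  route is recommended at that scale. The test suite exercises Monte-Carlo
  convergence on ≤ 4-vertex fixtures at `t = 2000, L ≤ 500` and the
  packaged-network simulated screen at `t = 10³, L = 40` (rank check; each
  realization already averages 10³ walkers, so the top-rank margin is many
  standard errors). `scripts/acceptance.py` runs the simulated screen at
  `t = 10³, L = 10³`.
* Ties in the screen ranking are broken by Python's stable sort on the
  (descending) `P̄` key, i.e. original vertex order.

## Limitations

* Edges are unweighted and unsigned; inhibitory interactions are
  represented no differently from stimulatory ones.
* The walk models diffusion of stimulation, not kinetics: `P̄` is a
  topological-dynamical impact score, not a prediction of cytokine levels.
* Only single-vertex knockouts are screened; combinatorial (pairwise)
  ablations and edge knockouts are out of scope.
* The packaged edge list is a transcription; its manifest is the contract
  for auditing it, and per-component numeric values move with it.
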