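# Methods

## Sequence-space coupling model

The coupling track implements classical mean-field direct coupling
analysis over a fixed 21-state alphabet (20 canonical amino acids plus
gap). Design choices that matter:

* **Alphabet and coercion.** Non-canonical symbols (X, B, Z, U, O, `.`)
  and anything unrecognized are coerced to gap and counted; lowercase is
  upper-cased. The model has exactly q = 21 states, so there is no
  "unknown" state. No columns are trimmed at read time.
* **Reweighting.** Identity threshold 0.8 (fraction of identical
  positions, gaps included). This is the standard DCA convention; it is a
  config parameter because family-specific redundancy structure can
  justify other values. The computation is exact O(M²L), chunked.
* **Pseudocount.** λ defaults to M_eff, the convention of mean-field DCA;
  λ is exposed because it trades regularization against bias. The
  pair-frequency diagonal is defined as P_ii(A,B) = δ_AB·P_i(A), which
  makes marginal consistency exact for every pair including i = j.
* **Gauge.** The mean-field inversion removes the gap state at every site
  (q − 1 = 20 states), making the connected-correlation matrix invertible
  given a pseudocount. Couplings e = −C⁻¹ are gauge-dependent up to
  row/column offsets; all downstream quantities (DI) are gauge-invariant
  because the two-site fit renormalizes marginals.
* **Direct information.** The auxiliary fields h̃ are fitted by
  alternating marginal-matching (Sinkhorn-style) updates, tolerance 1e-6
  on the max marginal error, max 500 iterations, hard error on
  non-convergence naming the pair. Logs are natural throughout (nats).
* **Ranking.** Minimum sequence separation 5; ties broken
  lexicographically by (i, j) so every ranking is deterministic.

## Contact definition

"Imposing a contact" means Cβ–Cβ distance ≤ 8 Å (Cα for glycine or when
Cβ is absent). Both the atom rule and the cutoff are recorded in the
contact map and configurable; 8 Å Cβ is the common evaluation convention
for coevolution-based contact prediction.

## Graph analyses

Coupled pairs define an undirected weighted graph (one node per residue,
weight = coupling score; duplicate pairs keep the max weight). Community
detection is Girvan–Newman: repeatedly remove the edge of globally
highest betweenness, recomputing betweenness after each removal, and
return the connected-component partition of maximal weighted modularity
seen along the sequence. Betweenness uses edge *length* = 1/weight for
coupling graphs (stronger coupling = shorter path); correlation networks
already carry a distance (−log|c|) and use it directly. Modularity always
uses the raw weights. Equal-betweenness ties remove the lexicographically
smallest edge, making the decomposition deterministic. Maximal cliques
are enumerated Bron–Kerbosch-style (via networkx) and validated in the
tests against exhaustive subset enumeration. Clique analysis runs on the
same top-N graph as community detection.

## Disorder consensus

Per-residue scores from any number of external predictors are averaged
(arithmetic mean over predictors that scored the residue; spread is the
population standard deviation). Classes: disordered iff mean > 0.5,
flexible iff 0.2 ≤ mean ≤ 0.5, ordered below 0.2 — both boundaries fall
on the flexible side, since "disordered" is defined strictly as *above*
0.5. Residues missing from every predictor are dropped with a warning;
pairs touching them are excluded from summary counts.

## Elastic network model

Anisotropic network model on Cα coordinates: springs between all pairs
within 10 Å, uniform spring constant 1.0 (dimensionless; only relative
magnitudes matter for correlations). Both are config-exposed; they are
the standard Cα-ENM choices. The network must be connected at the cutoff
(hard error otherwise). A connected non-collinear structure yields
exactly six near-zero eigenvalues (rigid-body modes; five for exactly
collinear toys), identified by |λ| < 1e-8·λ_max and excluded from all
statistics. Cross-correlations use equal-temperature 1/λ weighting over
the non-rigid modes — the Hessian pseudo-inverse — normalized to unit
diagonal. Metal ions are represented, when wanted, as extra network
nodes placed at the centroid of their coordinating residues
(`synthetic.add_crosslink`); this operationalizes "metal residence" as
extra local stiffness without any chemistry.

Variant naming: the packaged variant table assigns Cu-SOD1 = H120F and
Zn-SOD1 = H71F. The literature is not consistent about which of the two
histidines belongs to which mono-metallated form; both specs are shipped
by name so users can re-label without touching coordinates. Variant
structures are user-supplied; for testing, wild-type coordinates are
paired with the variant's sequence — side-chain identity does not enter
a Cα ENM, which is a documented limitation of the toy fixtures (real
variant models would come from homology modelling, which is out of
scope).

## Synthetic data: what it emulates and what it does not

* **Potts MSAs.** Sequences are Gibbs-sampled from
  P(s) ∝ exp(Σ h_i(s_i) + Σ J_ij(s_i, s_j)) with planted same-state
  couplings J = strength·I_q on disjoint pairs ≥ 5 positions apart. Each
  row is an independent chain run 50 full sweeps from a random start
  (chains vectorized across rows, never reused), which removes
  autocorrelation concerns at the lengths used (L ≤ 100). Near-duplicate
  rows (5% of positions re-randomized) exercise the reweighting; at the
  0.8 identity threshold they are guaranteed redundant with their
  parents. The standard benchmark is L = 50, q = 8, 10 planted pairs of
  strength 1.5, M = 4000. What this does *not* emulate: phylogenetic
  (tree-structured) correlation between rows, gap patterns, and
  heterogeneous conservation — so a perfect recovery here shows the
  estimator chain is correct, not that real-family inference is easy.
* **Toy chains.** Extended strand (3.8 Å Cα spacing), ideal α-helix
  (radius 2.3 Å, rise 1.5 Å, 100°/residue), and a mirror-image two-helix
  dimer whose monomer swap is an exact ENM symmetry (used to test
  exchange invariance of the cross-correlation matrix).
* **Disorder tables.** Per-predictor scores centred at 0.7 inside planted
  disordered stretches and 0.15 outside, with per-predictor offset and
  residue-level jitter, clipped to [0, 1]; consensus classification
  recovers the stretches to within ~2 residues at the edges.

## Published reference tables

The package ships the published top-10 MI and top-18 DI coupled pairs for
human SOD1 (with their printed mean disorder scores) as worked-example
inputs. Two caveats are recorded here deliberately: (a) the 18 DI pairs
cover **35** distinct residues, not 36 — residue 28 appears in two pairs,
and 36 counts pair slots; (b) the family-scale coupling scores themselves
are not desk-reproducible because the original alignment version,
pseudocount, identity threshold, and contact definition are unstated, so
the tables are used as fixed inputs to the graph/disorder machinery, and
the known family-scale clique memberships (MI: {63, 68, 70, 92, 96, 122};
DI: {60, 69, 113, 127}) are treated as documentation, not as a test —
they cannot emerge from the 18 printed pairs alone.

## Numerical conventions

Tolerances: frequency invariants 1e-10; DI fixed point 1e-6 (max 500
iterations); eigenvector orthonormality 1e-8; modularity recomputation
1e-10. Degenerate inputs: edgeless graphs give singleton communities with
Q = 0; graphs with < 3 nodes have zero betweenness; single-sequence
alignments are rejected for coupling analysis. Randomness enters only
through the synthetic generators, all driven by explicit integer seeds.

## Problem sizes

The benchmark and test problem sizes (M = 4000 × L = 50 Potts sampling,
≤ 30-residue toy chains, ≤ 16-node exhaustive graph oracles) were chosen
so that every oracle remains exhaustively checkable and the whole suite
runs in well under a minute on one core, while still being large enough
for the estimator asymptotics (sampling error ≪ planted effect sizes).
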