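# Methods

This note records the models, conventions and numerical choices behind
`phyloconsensus`, in the order the pipeline applies them, and what the
synthetic-data tests do and do not establish.

## Family curation

Input is an existing protein multiple sequence alignment; the package never
re-aligns. Three gates are applied in order: byte-identical ungapped
duplicates of an earlier record are dropped; records whose ungapped length
is outside `(1 ± length_tolerance) ×` the query's ungapped length are
dropped (default tolerance 0.2 — "excessively long or short" has no
standard definition, so the knob is exposed); records with identity to the
query below `min_identity` (default 0.5) are dropped. Identity is the
conventional MSA identity: matches divided by mutually non-gap columns, on
the given alignment. `'X'` residues are accepted on input but never count
as a match and never become a consensus residue. Filtering is idempotent
and the query is never removed; fewer than three survivors is an error,
since a consensus over two sequences is meaningless.

## Distance and tree

The pairwise metric is a p-distance variant suited to curated protein
families: the count of aligned columns where both sequences carry residues
and the residues differ, divided by the *shorter* sequence's ungapped
length. It is capped at 1. Dividing by the shorter ungapped length (rather
than by compared columns) slightly inflates distances between sequences of
unequal coverage; for families curated to ±20% length and >50% identity
the difference is marginal, and the definition has the advantage of being
exactly the quantity the weighting downstream was designed around.

Neighbor joining is the standard Saitou–Nei agglomeration: join the pair
minimizing `Q(i,j) = (n−2)d(i,j) − r_i − r_j`, assign limb lengths by the
usual formulas, reduce the matrix, finish with the three-node closed form.
Two deliberate conventions: ties in the Q minimum go to the lowest index
pair in input order (determinism; permuting the input permutes the result
consistently), and negative limb estimates — an NJ artifact on
non-additive matrices — are clamped to zero with the total clamped
magnitude kept on the tree object (`clamped_deficit`) rather than silently
discarded. On additive matrices the implementation reproduces the
generating tree and metric exactly; this is tested against brute-force
topology enumeration with least-squares edge fitting up to six taxa, and
against scikit-bio's independent NJ on perturbed matrices.

Rooting places the root on the outgroup's terminal edge, by default at its
midpoint (`split_fraction` exposed, since "attach at the basal node" admits
any split); leaf-to-leaf path lengths are invariant to this choice, and the
weights below depend on the outgroup edge only through the root position.

## Sequence weights

The goal of the weighting is statistical: near-identical sequences should
share, not multiply, their vote in the consensus. The default strategy
(`equal-split`) distributes each edge's length equally among the child
*branches* at every node below it; a leaf's raw weight is the sum of its
shares over the edges on its root-to-leaf path, and weights are normalized
to sum to one. This scheme has an exact de-biasing guarantee: attaching k
copies of a leaf at zero distance, in any arrangement, leaves the copies'
combined normalized weight equal to the original leaf's weight, for any k
— the share entering a subtree is fixed by the splits above it and is
merely subdivided inside. Scale invariance (branch lengths × c) is exact
as well.

The better-known Gerstein–Sonnhammer–Chothia rule — divide each edge's
length by the number of leaves below it — is available as
`strategy="gsc"`. The two coincide on balanced binary subtrees; under
duplication GSC's invariance is only approximate (a duplicated pair's
combined weight drifts upward, e.g. 0.30 → 0.33 on the three-leaf
caterpillar), which is why it is not the default. The exact algebra of
tree-weight schemes varies across the literature and published
descriptions are often incomplete; the strategy is therefore a documented,
swappable function rather than a hard-coded formula.

Leaves at zero total path length receive ε = 1e-8 × the mean raw weight
before normalization, preserving positivity without reordering. An
all-zero-length tree yields uniform weights with a warning. The outgroup
exists only to place the root: it is excluded from the weights and hence
from the consensus.

## Consensus calling

Weighted residue frequencies are computed per alignment column and indexed
by 1-based ungapped query position (mutation notation `D17V` = query Asp at
position 17 → consensus Val). Gaps and `'X'` accumulate in a separate
`gap_mass`; frequencies plus gap mass sum to one per position. A candidate
site requires the top residue (gaps excluded) to differ from the query and
to exceed the cutoff — default 40%, strict inequality — measured against
*total* weight including gap mass, the conservative reading of "frequency
among aligned sequences"; `cutoff_basis="residues"` switches the
denominator to non-gap weight. An argmax tie emits nothing (no unambiguous
consensus). Candidate count is anti-monotone in the cutoff by
construction.

## Structural screening

Two geometry-only exclusion criteria, applied to a PDB structure of the
query with a user-declared active-site residue list (the package consumes
structures; it does not build homology models):

* **Active-site distance** — minimum heavy-atom-to-heavy-atom distance
  from the candidate residue (backbone included) to any active-site
  residue; the candidate must be *strictly greater* than `min_distance`
  (default 6.0 Å) away. The measurement definition is a package choice:
  published screens rarely state theirs, and tabulated distances are
  homology-model-dependent, so distances from different models are
  comparable only in threshold behavior.
* **Side-chain bonding** — the candidate is rejected if its side-chain N/O
  atoms sit ≤ 3.5 Å from any N/O atom of another residue (hydrogen bond by
  distance; no angle term, hydrogens ignored — homology models lack them),
  or if a basic side-chain nitrogen (Lys NZ, Arg NE/NH1/NH2, His ND1/NE2)
  pairs with an acidic carboxylate oxygen (Asp OD1/OD2, Glu OE1/OE2) at
  ≤ 4.0 Å (salt bridge; takes precedence in the report). Backbone atoms of
  the *partner* count — the criterion protects interactions made by the
  candidate's own side chain, wherever they land.

Residue identity at every mapped position is checked against the query
letter and a mismatch is a hard error: an off-by-one numbering offset
would silently corrupt every distance. Altloc atoms keep the
highest-occupancy conformer. Filtering sets a status
(`rejected_distance` before `rejected_bonded` before `passed`) and deletes
nothing, so the audit trail survives into the report. Statuses depend only
on geometry, are invariant to rigid-body transforms, and tightening the
radius can only convert `passed` → `rejected`.

## Stability fits

* **Half-life.** Ordinary least squares of `ln(y/100)` on time; `k` is the
  slope and `T½ = −ln 2 / k`; non-negative slope is a "no decay" error.
  The fit window defaults to points with ≥ 5% of initial activity — the
  log transform makes near-zero activities dominate the residual — with an
  explicit time window available. Non-positive activities are dropped with
  a warning.
* **T50¹⁵.** Activity is renormalized so the lowest-temperature point is
  100%, then fitted with the Boltzmann sigmoid
  `y(T) = A₂ + (A₁−A₂)/(1+exp((T−T50)/dT))` by Levenberg–Marquardt from a
  deterministic start (plateaus at the data extremes, T50 at the
  half-activity point, dT = 2 °C). The curve must span both plateaus
  (>80% and <20%) and must fall with temperature.
* **Tm.** A polynomial (degree 9 by default) is least-squares fitted to the
  350/330 ratio over a ±12 °C window centered on the coarse
  finite-difference slope maximum, and Tm is the argmax of the fitted
  first derivative on a 0.01 °C grid. The windowing is essential: one
  global polynomial over a 75 °C ramp cannot follow a sharp unfolding
  transition and rings at the ramp ends (error ~0.3–0.5 °C or a spurious
  edge maximum; windowed, noise-free recovery is within 0.05 °C). A
  derivative maximum at the edge of the ramp produces a boundary warning.
* **Summaries.** Fold improvement = variant T½ / reference T½ at the same
  stress temperature, reported to two decimals below 10 and one decimal at
  or above (the convention used in the variant tables this package
  reproduces); success rate = integer-rounded percentage of variants with
  fold > 1. Half-lives are reported to 0.1 min and temperatures to 0.1 °C.

## Synthetic data

The family simulator evolves an ancestral sequence down a tree with
site-independent substitution and no indels; per edge of length `l` a site
changes with probability `(19/20)(1 − exp(−rate·l·20/19))`, the exact
endpoint distribution of a Poisson jump process with uniform replacement
over the other 19 residues. This gives closed-form divergence expectations
for tests. Defaults mirror the intended application scale: families of ~24
homologs of length 404. The bias construction plants a clade-specific
substitution at a fully conserved site and then duplicates the clade's
leaves (branch length 1e-4) until the clade holds an absolute majority —
the strongest version of database redundancy, with known ground truth at
one position. Random trees draw edge lengths uniformly in
[0.5, 1.5] × mean, bounded away from zero so every split is resolvable in
principle; topology-recovery rates are statements about this regime, not
about star-like radiations.

What the generator deliberately omits: indels, rate heterogeneity across
sites, and empirical substitution matrices (JTT/WAG), plus any correlation
between sites. Passing tests therefore establish the correctness of the
algorithms under the stated model, and the direction and mechanism of the
de-biasing effect — not that any particular real family will yield a given
hit rate. Gap handling is exercised by hand-built alignments instead.

Assay generators produce first-order decay with multiplicative Gaussian
noise, Boltzmann inactivation ladders (35–70 °C in 2.5 °C steps) with
additive noise, and two-state melt ratio curves on a 1 °C grid (20–95 °C)
with optional linear baselines; equal baseline slopes leave the derivative
argmax at the midpoint exactly.

## Validation scales

The default test suite and `scripts/acceptance.py` use: 100 seeded
replicates for fit-recovery statistics (typical errors ~2.7% on T½ at 3%
multiplicative noise, ~0.10 °C on T50 at σ = 2 activity-%, ~0.06 °C on Tm
at σ = 0.002 ratio units); 50 seeds of 8-leaf, 404-site families for NJ
topology recovery; 20 seeds of the bias construction for the weighted vs
uniform consensus comparison; exhaustive topology enumeration up to 6
taxa. These sizes give stable statistics while keeping the full suite in
the low seconds.

## Known limitations

* The distance metric is uncorrected for multiple hits; at the intended
  >50% identity range this is benign, but the tree is not meant for deep
  phylogenetics (no model correction, no bootstrap support).
* Hydrogen-bond detection is distance-only; a proper donor–acceptor-angle
  criterion would reject some of what this accepts. The screen errs on the
  side of excluding candidates.
* Combinatorial variant planning (which singles to stack next) is reported
  only as ranked candidates; the greedy stacking used in practice depends
  on wet-lab measurements between rounds and is out of scope.
* T50/Tm uncertainty is the fit's, not a replicate-based error bar; the
  package does not model between-replicate variance.
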