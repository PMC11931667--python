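# Methods

This note documents the models, estimators and numerical choices behind
`ensmut`, and what the synthetic-data tests do and do not establish about
real trajectory data.

## Conformational ensembles

An ensemble is an `(n_frames, n_atoms, 3)` coordinate stack over a single
atom table.  Multi-model PDB is the interchange format; residue numbering
is preserved exactly as authored (the hLAMAN tables use precursor
numbering that includes the signal peptide, e.g. C55), and no renumbering
ever happens on read.  Waters and monoatomic ions are dropped at read
time.  Equilibration trimming is left to the caller: published protocols
are inconsistent about how much of the early trajectory to discard, so
the reader performs no implicit trimming.

Dihedrals (φ, ψ, χ1–χ5) are computed in float64 with the standard
projection/arctan2 torsion formula on the canonical domain [−180, 180)
(+180 maps to −180).  Terminal residues lack φ or ψ; Gly and Ala carry no
χ.  The test suite checks the extraction against an independent
plane-normal torsion construction to 1e−6°.

RMSF defaults: frames are least-squares superposed on Cα (two rounds of
the iterative-mean Kabsch fit), and the per-residue value is the mean of
the heavy-atom RMSFs.  The atom selection and alignment reference are not
standardized in the field's reports, so both are explicit parameters.

Frame subsampling is evenly spaced by default (first and last frames
included, n = 60, matching the stability-analysis protocol) with a seeded
random alternative.

## Synthetic data with closed-form truth

- **Coupled dihedrals** come from a latent Gaussian copula: latent normals
  with prescribed correlation ρ are mapped through the normal CDF to
  uniform angles on [−180, 180).  MI is invariant under monotone marginal
  transforms, so the pairwise MI is exactly −½ ln(1−ρ²) nats and the
  marginals are exactly uniform on the circle.  Optional wrapped-normal
  noise (`concentration`) can only lower the realized MI; the default adds
  none, keeping the ground truth exact.
- **Gaussian-fluctuation ensembles** add correlated normal displacements
  to a base structure.  The ground-truth RMSF of residue *i* is
  √(Σ coordinate variances of its atoms / n_atoms); isotropic σ per
  coordinate gives σ√3.  For heterogeneous per-atom σ within one residue
  the library's mean-of-atom-RMSFs differs from this RMS form, so the
  recovery tests use per-residue σ, where both coincide.
- **Toy complexes** are ideal poly-Ala α-helices (φ = −57°, ψ = −47°)
  built by natural-extension (NeRF) placement with standard backbone
  geometry, axes aligned to z and placed at a prescribed separation.
  Optional ASP/LYS substitutions (minimal side chains) and per-chain
  rotations let tests engineer salt bridges across an interface.
  Inter-atomic distances below 1 Å raise an error.
- **Mutation catalogs** are schema-valid random tables, byte-identical
  under a fixed seed.

What these generators do *not* emulate: force-field energetics, solvent,
glycans, metal sites, or the long-time correlation structure of real MD.
Passing the recovery tests shows the estimators are correctly implemented
and calibrated on known ground truth, not that any particular biological
conclusion follows from a given trajectory.

## Stability distributions

The ensemble treatment is scorer-agnostic: any callable mapping
(frame, position, wild type, mutant) to kcal/mol works, with the contract
that identity substitutions score exactly 0.  The built-in surrogate is a
deliberately simple residue-level model —

- contact term: Δ over neighbors within 8 Å (side-chain centroid
  distance) of a potential built from hydropathy products and formal
  charges,
- hydrophobicity transfer: k·(b₀ + burial)·Δhydropathy, with burial the
  neighbor count saturating at 12 and b₀ a baseline so surface sites keep
  a reduced transfer cost,
- volume clash: burial-weighted penalty for over-filling the site,
- backbone strain: a penalty for mutating into Pro outside φ ≈ −60° and
  for removing Gly at positive-φ backbone conformations (the glycine-only
  region).

All constants live in `DEFAULT_SCORER_PARAMS`.  The surrogate exists to
exercise the distribution machinery (mean, population SD, multimodality);
it is not a calibrated force field, and external per-frame ΔΔG tables can
be imported through the same summary path.  SD is the population SD
(divide by n).  Mode counting smooths the per-frame values with a
Gaussian KDE (Silverman bandwidth by default) and counts density peaks,
discounting bumps below 2% prominence of the global maximum, which
sampling noise produces in the far tails.

## Dihedral mutual information

Equal-width circular histograms on [−180, 180), 50 bins by default, give
plug-in entropies in nats.  Normalization is MI / min(H(x), H(y)), chosen
because it realizes an exact [0, 1] coupling scale (1 for any
deterministic monotone relation); the value is defined as 0 when either
marginal entropy vanishes.  Residue-level coupling is the **sum** of
normalized MI over all dihedral pairs of the two residues, so totals may
exceed 1; only report integration rescales them.  Each matrix is tagged
with the normalization scheme.

The plug-in estimator has a positive bias of roughly (m−1)²/2N nats on
independent data (≈ 0.012 at 50×50 bins and 10⁵ frames).  An optional
leave-one-out jackknife correction (`jackknife=True`) removes this floor
(measured ≲ 0.0004 nats) at modest cost; the default remains uncorrected.
Active-site residues are flagged in coupling totals and excluded from
group statistics — their zeros in the descriptor table are a reporting
convention, not a measurement.

## Bond-to-bond propensity

Nodes are heavy atoms; edges carry positive interaction magnitudes:
covalent bonds from residue connectivity templates (element-pair bond
energies, with an element-distance heuristic fallback for unknown
residues), hydrogen bonds by donor–acceptor geometry (≤ 3.5 Å, 12-10
potential with equilibrium distance 2.9 Å and well depth 5 kcal/mol,
cos² angular factor about the ideal 120° donor–acceptor–antecedent
angle), screened Coulomb between charged side-chain atoms ≤ 6 Å
(ε(r) = 4r), and constant-depth hydrophobic contacts between apolar
carbons ≤ 5 Å.  All constants sit in one table
(`ENERGY_GRAPH_PARAMS`).

The transfer matrix M = W B L⁺ Bᵀ W is never materialized: per source
edge the grounded Laplacian (one node of the source's component removed)
is solved with a shared sparse LU factorization; the constant-vector
ambiguity of L⁺ cancels in the edge differences.  The contract — equality
with an explicit dense pseudoinverse computation to 1e−8 — is enforced in
the tests over random graphs.  Two degenerate regimes are handled
explicitly: edges that carry no flow (dangling trees) are clipped to
exact zero below 1e−12 of the maximum, and a source consisting only of
bridge edges (through which all injected flow must return) yields an
all-zero non-source propensity vector with a warning instead of a
noise-normalized one.

Quantile scores correct the strong distance decay of raw propensities:
linear quantile regression of log₁₀ propensity on the distance to the
nearest source atom, over the grid 0.01…0.99 (step 0.01); an edge's
score is the largest quantile level whose fitted line at the edge's
distance lies at or below the edge's value, and a residue's score is the
score of its maximum-propensity edge.  Log-propensities are rounded to 9
decimals before fitting so that numerically equivalent inputs (e.g.
uniformly rescaled weights) give bitwise-identical scores.  Snapshot
averaging uses 9 randomly selected frames by default, aggregated by the
mean.

## Suboptimal paths

Features are the sin/cos pair of each dihedral series (linearizing the
circular variables); the residue-level correlation is the maximum |r|
over cross-feature pairs with unit diagonal.  Edges require both a
contact (minimum heavy-atom distance ≤ 6 Å, evaluated on the
ensemble-average structure by default, or as a ≥ 50% per-frame contact
fraction) and |C| ≥ 0.25; the weight is −log |C|.  The k = 500 shortest
loopless paths are generated by a loopless deviation search; paths tied
with the k-th weight are absorbed and the final order is (weight,
lexicographic node sequence), making the output deterministic.  The
implementation contract is equality with brute-force enumeration of all
simple paths on small graphs.  Residue indices are assumed unique across
the structure (true for precursor numbering; multi-chain toys with
repeated indices should use single chains for path analyses).

## Interface energetics

Per frame, every interchain heavy-atom pair within 12 Å contributes a
Lennard-Jones term (united element radii, fixed well depth) plus a
Coulomb term with distance-dependent dielectric ε(r) = 4r
(332.06·q₁q₂/(4r²) kcal/mol), and pairs within 4.5 Å add a constant
desolvation proxy.  Each pair term is split half/half between the two
residues, so the per-residue decomposition sums to the chain-pair total
exactly (enforced to 1e−6 per frame).  The model's purpose is ranking
and decomposition; absolute energies are not comparable to any
particular force field.

## Descriptor integration

Normalization is division by the series maximum, or truncation at a cap
followed by division by the cap (stability mean and SD use the
20.35 kcal/mol cap; capped entries are flagged and map to exactly 1).
A separate plotting-only exclusion threshold (50 kcal/mol) exists for
bar-chart export and never modifies data.  Group summaries are
component-wise medians; active-site-flagged profiles are excluded from
the MI and propensity medians but kept for the stability medians.

The rank-sum test returns the exact two-sided p by enumeration of all
rank assignments when n₁+n₂ ≤ 12 without ties, otherwise the normal
approximation with tie and continuity corrections.  Classification of
unassigned variants is the nearest group median in Euclidean distance on
the normalized 4-vector; exact ties are reported as unresolved, and the
full distance table always accompanies the label because the rule is a
package choice, not an established convention.  Quadrant labels compare
MI and propensity to the 0.5 midpoint of the normalized scale, with the
boundary assigned to "high".

## Problem sizes and limitations

Tests and the acceptance script run on desk-scale inputs: toy complexes
of 8–20 residues, Gaussian ensembles up to 20,000 frames, copula series
of 10⁵ frames, random graphs up to 200 edges, path graphs up to 50
nodes.  These sizes exercise every code path and calibrate the
estimators against closed-form truth; descriptor values for the real
enzyme require externally produced trajectory ensembles as input.  The
surrogate stability scorer and the simplified interface model are not
substitutes for calibrated force fields, and the nearest-median
classifier encodes one defensible reading of "similar radar profile",
not the only one.
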