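# Methods

`enmpcn` analyses a protein complex, coarse-grained to one node per
residue, through two complementary network lenses and then compares
them. This note records the models, the parameter choices, the
numerical conventions, and what the synthetic fixtures do and do not
establish.

## Coarse-grained representation

A structure is reduced to an ordered list of residues (chain, residue
number, insertion code, name), the Cα coordinate of each residue, and
the residue's heavy-atom list. Parsing keeps the first model of a PDB
file only, keeps the highest-occupancy alternate location, drops
hydrogens, drops HETATM records (heme groups, waters and ligands are
not network nodes), and drops residues without a Cα with a warning.
Side-chain atom counts are heavy atoms excluding the backbone set
{N, CA, C, O, OXT}; glycine therefore counts zero. The concatenated
residue index is contiguous 1..N across chains in every user-facing
table. mmCIF input, assembly expansion, and sequence alignment are out
of scope: when two conformations are compared, residues are matched by
(chain, number, insertion code), which is adequate for crystal forms
of the same protein that share numbering.

## Elastic network models

**GNM.** Residues within `gnm_cutoff` (default 7 Å, inclusive) are
connected by springs of uniform constant γ. The Kirchhoff matrix Γ has
−1 for contacts and the contact degree on the diagonal; its row sums
are exactly zero. Square fluctuations over a mode subset are
⟨ΔR_i²⟩ = (3kT/γ) Σ_k λ_k⁻¹ u_k[i]²; over all nonzero modes this is
the Γ pseudoinverse diagonal. Cross-correlations C_ij normalize the
mode-restricted covariance, so the diagonal is exactly 1 and values
lie in [−1, 1]; residues with zero partial fluctuation in the chosen
subset yield NaN (undefined), never 0. The default scale 3kT/γ = 1
reports relative units; absolute scaling is the caller's affair.

**ANM.** Residues within `anm_cutoff` (default 13 Å) contribute 3×3
super-elements −γ R⃗_ij R⃗_ijᵀ / R_ij² to the 3N×3N Hessian, whose
diagonal blocks close each block row to zero. The Hessian annihilates
rigid translations exactly by construction and rigid rotations at
equilibrium to roundoff.

**Zero modes and numbering.** Eigenvalues below 1e-8 × λ_max are
rigid-body modes: exactly one for a connected GNM, exactly six for a
non-degenerate 3-D ANM. Any other count raises an error rather than
being silently absorbed — a disconnected contact graph is a modelling
problem the user must see. "Mode 1" is everywhere the slowest
*nonzero* mode. Eigenvector signs are arbitrary, so all overlaps are
reported as absolute values.

**Overlaps and conformational change.** Two conformations are
superposed by least-squares rigid-body fitting on matched Cα
(implemented via `scipy`'s rotation alignment; the test suite checks
it against an independent quaternion solver). The residual field Δr is
the observed deformation. Per-mode overlaps are |Δr·u_k|/|Δr| and the
cumulative overlap is CO(m) = √(Σ_{k≤m} overlap²); a configuration
switch exposes the unsquare-rooted running sum for users who prefer
that convention. Cross-structure mode overlaps recompute both mode
sets on the matched-residue intersection so the bases are
dimensionally consistent. One caveat worth knowing: for ANM mode sets
of two *different* conformations the completeness sum Σ_l O(u_k,v_l)²
falls short of 1 by O(θ²) for a relative rotation θ, because the two
Hessians' rigid-rotation null spaces differ; the identity is exact for
GNM pairs, whose null space (the constant vector) is
conformation-independent. CO over the full basis still reaches 1
because superposition removes the rigid component of Δr.

**Hinges and hot spots.** Hinge sites of a slow mode are residues in
the near-zero band (|u_i| < 0.05·max|u| by default) or at sign
changes between chain neighbours (the smaller-amplitude residue of the
crossing pair). Hot spots are local maxima, within a chain, of the
square-fluctuation profile of the two highest-frequency modes,
exceeding mean + 2 SD of that profile; both the mode count and the
peak rule are configurable.

## Markov propagation

The affinity between residues i and j is a_ij = N_ij/(N_i N_j), where
N_ij counts heavy-atom pairs within 4 Å (one atom from each residue;
KD-tree accelerated, brute-force-verified in tests) and N_i is the
side-chain heavy-atom count, guarded to min 1 so glycine stays finite.
The square-root normalization N_ij/√(N_i N_j) and a side-chain-only
contact count are available as options. The transition matrix
m_ij = a_ij/d_j is column-stochastic with stationary distribution
d/Σd.

Hitting times use the closed form
H(i,j) = Σ_k [Γ⁺_kj − Γ⁺_ij − Γ⁺_ki + Γ⁺_ii]·d_k with Γ⁺ the
Moore–Penrose pseudoinverse of the graph Laplacian diag(d) − a of the
affinity graph. That Laplacian — not the 7 Å GNM Kirchhoff matrix —
is the default because it is the generator consistent with the
transition matrix above: it is the choice that reproduces Monte-Carlo
first-passage simulations (verified within 2 % in the tests) and
satisfies the commute-time/effective-resistance identity
C = 2|E|·R_eff on unweighted graphs. Passing the GNM Kirchhoff matrix
instead is supported (`--laplacian gnm`) for users who want the
contact-topology variant. The result is invariant to the additive
gauge of the pseudoinverse (adding a constant to every entry cancels),
which the tests exercise directly.

Commute times C(i,j) = H(i,j) + H(j,i) are symmetrized round trips;
⟨C(i)⟩ is the row mean excluding the diagonal. Candidate allosteric
residues are strict local minima of ⟨C(i)⟩ per chain over a 5-residue
window (ties to the lower index), ranked by ⟨C(i)⟩ ascending.

## Protein contact network

Edges connect Cα pairs whose distance lies in the closed window
[4, 8] Å: the lower bound excludes covalently bonded sequence
neighbours (~3.8 Å), the upper bound keeps significant non-covalent
contacts. Degree, betweenness (Brandes, unnormalized, unordered pairs
counted once) and closeness (1/Σ sp, not the (N−1)-scaled variant) and
the characteristic path length are computed on the connected network;
a disconnected network is refused unless the caller opts into
largest-component analysis, in which case excluded nodes carry NaN.

**Spectral clustering** is recursive two-way bisection: each module's
induced subgraph is split by the sign of the Fiedler vector of
L = D − Ad (we use the positive-semidefinite sign convention; the
split is identical to the Ad − D variant). The Fiedler vector's sign
is normalized (first nonzero component positive) and exact zeros join
the non-negative side, so partitions are bit-reproducible; a
disconnected module splits by connected components (largest versus
rest) before any eigenvector is consulted. Two iterations (up to four
modules) is the default, matching a tetramer's chain architecture.

**Cartography.** The participation coefficient defaults to the
standard multi-module form P_i = 1 − Σ_s (k_si/k_i)²; the single-term
own-module variant 1 − (k_si/k_i)² is available as `p_form="paper"`
(the two coincide for the dominant P = 0 population and for two-module
nodes). The z-score standardizes the intramodule degree k_si against
the node's own cluster by default (population SD), with a
whole-network option. Regions: hubs have z > 2.5; non-hubs split at
P = 0.05 / 0.625 / 0.8 into R1–R4 and hubs at P = 0.3 / 0.75 into
R5–R7, with half-open intervals closed on the left so boundary points
are assigned deterministically. R4 ("non-hub kinless") nodes are the
candidate inter-module communicators.

## Comparison layer

Per-residue columns — GNM all-mode mean fluctuations (MF), average
commute time (CT), degree, betweenness, closeness, P and z — are
aligned on the shared index; the report computes sample Pearson
correlations for closeness/MF, betweenness/MF, P/MF and P/CT with
pairwise deletion of undefined entries, and Jaccard indices between
the key-residue sets (hinges, commute minima, R4 and R5 nodes by
default; any named sets — e.g. ANM hot spots — can be supplied). MF
defaults to the GNM profile because GNM is the fluctuation workhorse
at this coarse-graining; an ANM-based MF can be substituted by the
caller. Report generation is pure: identical inputs give byte-identical
files.

## Synthetic fixtures

The toy tetramer is a dimer-of-dimers of four ideal helices (two
14-residue "α"-like, two 12-residue "β"-like chains) with an exact
two-fold axis (the 180° image is computed with an exact sign-flip
matrix, so symmetry assertions hold to the bit). Intra-dimer packing
is tighter than the inter-dimer interface, making the counter-torsion
of the two dimers — the deformation produced by the two-state
generator — a soft direction, while keeping the structure connected at
the 4 Å atom-contact, 7 Å GNM, 13 Å ANM and 4–8 Å PCN levels.
Pseudo-side-chains of 0–3 atoms per residue (cycling ALA/GLY/SER/LEU)
exercise the atom-contact machinery including the glycine N_i = 0
guard.

What the fixtures do **not** emulate: realistic packing density and
secondary-structure diversity, sequence-dependent contact energies,
crystallographic artefacts (missing residues, alternate conformers
beyond the parser tests), or the size (N = 570) of a real tetramer.
Passing fixture tests therefore establishes the correctness of the
mathematics and the determinism of the pipeline, not biological
accuracy of predictions on any particular protein. The hemoglobin
checks in the acceptance tests run the identical code path on PDB
entries 2dn2/2dn1/2dn3 when those files are available.

Problem sizes used by the test-suite and the acceptance script: toy
tetramer N = 52 (150 ANM modes), random graph fixtures of 4–12 nodes
(hundreds of draws for property tests), Monte-Carlo oracle 10⁵ walks.
These sizes make every oracle exact or tight while keeping the whole
suite in the seconds range.

## Known limitations

* Correspondence between conformations is by residue identity, not
  alignment; structures with different numbering schemes must be
  renumbered upstream.
* ANM cross-conformation overlap matrices are not exactly complete
  (see above); interpret row sums of squared overlaps as ≤ 1.
* The commute-time model treats the complex as a single connected
  contact graph; ligand-mediated paths are invisible because HETATM
  records are excluded.
* Plotting is deliberately absent: all outputs are TSV/JSON, intended
  for downstream tools.
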