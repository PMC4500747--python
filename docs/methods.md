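# Methods

## 1. Tissue geometry

The tissue is a 2-D sheet of rectangular myocytes (default
101 × 24.1 μm, depth equal to width) laid out brick-and-mortar style:
adjacent columns are shifted by a transverse offset (default 50 % of the
cell width) and adjacent rows by a longitudinal offset (default 20 % of
the cell length), so cell ends abut two neighbours and lateral borders
abut staggered neighbours. Each cell polygon is triangulated (fan
triangulation of the notched footprint) for the intracellular finite
elements.

The membrane of each cell is divided into boundary *patches*, classified
as **junctional** (shared with an abutting neighbour across a 15 nm
cleft) or **lateral** (facing the 100 nm-wide interstitium). Junctional
interfaces are subdivided into `junctional_subdivisions` sub-segments
(default 5; trend signs converge by 3–5) so that the cleft potential can
vary along the intercalated disk. Each patch carries an area
(perimeter length × depth); total membrane area per cell is conserved,
`2(L+W)·D`.

## 2. Extracellular network

The extracellular space is a resistor network on cleft/interstitial
nodes placed at patch midpoints and shared polygon vertices. Each
sub-segment contributes a conductance

    g = σ_eff · w · D / ℓ_half

where `σ_eff` is the effective extracellular conductivity (junctional
17.8 mS/cm, lateral 159.1 mS/cm by default), `w` the cleft width (15 nm
junctional, 100 nm lateral), `D` the sheet depth, and `ℓ_half` the
half-length of the sub-segment. One extracellular node is grounded
(gauge fixing); membrane potential `V_m = φ_i − φ_e` is invariant under
that choice (verified by a gauge-shift test).

## 3. Membrane and channels

The ionic model is a two-current Hodgkin–Huxley-type membrane: a fast
sodium current `I_Na = g_Na·m³·h·(V − E_Na)` with Ebihara–Johnson-style
rate functions (the `α_m` removable singularity at −47.13 mV is handled
analytically) and a linear background potassium current. Gates advance
with the Rush–Larsen exponential update, exact for frozen voltage.

Sodium conductance is partitioned between junctional and lateral
membrane at fixed total: the **uniform** distribution places 11 % of the
conductance-area product on junctional membrane (its natural area
share), the **polarized** distribution 90 %. A lone cell with no
junctional membrane falls back to an all-lateral distribution.

## 4. Discretization and solver

Assembling intracellular FEM stiffness `K`, gap-junction coupling `G`
(conductance ḡ_j × shared junctional area, applied between patch nodes
of paired cells), extracellular Laplacian `L_e`, and the patch
capacitance map `S` gives the DAE system

    M du/dt + A u + Sᵀ diag(area) I_ion(V, gates) = f(t)

with `M = Sᵀ C S` (singular — the extracellular space stores no
charge) and `A = blockdiag(K + G, L_e)` plus the membrane coupling
blocks. Time stepping is Crank–Nicolson on the linear part with the
ionic current evaluated at the start of step (gates updated first by
Rush–Larsen), a gauge row at the reference extracellular node, and a
cached sparse LU factorization. Units: mV, ms, mS, μF, μA, cm.

Verified invariants: hand-assembled stiffness oracle, zero row sums,
symmetry, uniform-potential nullspace, per-step charge residual
< 1e-8, passive decay `τ = C_m/G_leak` within 5 %, CV self-convergence
< 2 % under dt halving at the default dt = 0.005 ms.

## 5. Conduction velocity estimation

Activation time is the time of maximum central-difference dV/dt; traces
with peak-to-peak amplitude below a threshold count as not activated.
CV is obtained by least-squares fitting activation time against distance
along an on-axis ray through the pacing origin, excluding two near-field
sites at each end and requiring at least five sites; AR = CV_L/CV_T.
On analytic elliptical maps the estimator recovers the generating
velocities to machine precision and the AR within 5 % at 0.5 ms
activation-time noise.

## 6. Cluster association pipeline

Images are thresholded with Otsu's method (exact integer-bin search for
integer images, 256 bins otherwise; foreground is strictly above the
threshold; ties resolve to the lowest threshold), segmented with
8-connected component labelling, and Nav1.5 clusters are classified
against Cx43 clusters by minimum edge-to-edge distance computed from
Euclidean distance transforms: **overlapping** (shared pixels),
**perinexal** (edge distance ≤ 200 nm), or **distal**. Per-Cx43 partner
counts are histogrammed as 0 / 1 / ≥2. The Otsu and component routines
are tested against exhaustive-search and flood-fill oracles.

Synthetic two-channel generators place elliptical clusters with
specified class geometry (contact, 100 nm, 400 nm gaps by default),
iteratively nudging centers until the rasterized edge distance matches
the intended one within half a pixel, and optionally apply Gaussian blur
(FWHM → σ = FWHM/2.3548) and background noise. With a 22 nm FWHM blur
the pipeline recovers classes placed ≥50 nm from the 200 nm boundary
with ≥95 % accuracy over 20 seeds.

## 7. Limitations

- **Sub-threshold ephaptic hand-off at nominal coupling.** With the
  default parameter set (ḡ_j = 100 mS/cm², two-current membrane), the
  cleft potential excursion self-limits at about −6.5 mV and the
  post-junctional membrane reaches only about −63 mV when gap junctions
  are removed — roughly 8 mV short of threshold. Ephaptic interaction
  therefore *modulates* but does not *carry* conduction here. A direct
  consequence is that raising extracellular conductivities (the edema
  intervention) relieves cleft self-attenuation and interstitial loading
  and speeds transverse conduction in both channel distributions,
  rather than selectively slowing the polarized model. This sign is
  robust across wide sweeps of extracellular conductivity scale
  (0.3–30×), ḡ_j (0–100), g_Na (0.4–2.5×), g_K, intracellular
  conductivity, h-gate kinetics, activation shifts, and cleft-mesh
  refinement. An ephaptic-aid regime does exist in this model, but only
  below roughly half-nominal gap-junctional coupling. Three acceptance
  sub-assertions that presuppose the opposite sign at nominal coupling
  are left failing by design, with passing sub-assertions split out.
- The membrane model is a minimal two-current description; late
  currents, calcium dynamics, and restitution are out of scope.
- The sheet is 2-D with a fixed depth; no transmural structure.
- Cleft widths are static — no dynamic perinexal swelling.
- The image pipeline assumes well-separated clusters; heavily
  overlapping plaques merge into single components.
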