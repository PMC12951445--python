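# Methods

`flavotune` implements the classical-electrostatics half of a
spectral-tuning analysis for flavin-binding photoreceptor (LOV) domains: how
a protein's charge distribution shifts the energies of the chromophore's
bright singlet (S1 π,π\*) and the N5-lone-pair triplet (Tn n,π\*), and hence
the singlet–triplet gap that gates intersystem crossing. The quantum-chemical
and molecular-dynamics engines that produce the underlying state charges and
conformational ensembles are deliberately out of scope; their outputs are
inputs here, and a synthetic-data module supplies physically structured
stand-ins so every stage runs at desk scale.

## Surfaces

Probe and projection surfaces are unions of per-atom spheres at `k` times
the van der Waals radius of each heavy atom (`k = 2` for tuning maps,
`k = 1` for potential projections; hydrogens never seed or prune a surface).
Each sphere carries a deterministic golden-angle (Fibonacci) lattice with
`round(4π(k·r)²·density)` points, and candidates strictly inside another
heavy atom's `k`-sphere (distance < k·r − 10⁻⁹ Å) are removed. The lattice
makes point sets exactly reproducible, which the test suite exploits; the
physical map values are insensitive to the sampling density, but point
*counts* are density-dependent and should not be compared across densities.
Default density is 1 point/Å², giving a few hundred points for a
lumiflavin-sized chromophore.

Radii come from a bundled Amber-style table (Rmin/2 values; C 1.908 Å,
N 1.824 Å, O 1.6612 Å, …), overridable via a user table, since published
PDB→PQR conversions do not agree on one radius set.

## Potential fields

The protein's electrostatic potential is modelled as a screened Coulomb sum
over fixed partial charges in a uniform dielectric:

    φ(p) = (k_C / ε·kT) · Σᵢ qᵢ · exp(−κ·dᵢ)/dᵢ      [kT/e]

with κ = 0, ε = 1 the vacuum default. All Coulomb prefactors derive from a
single CODATA value (k_C = 14.399645 eV·Å·e⁻², 1 eV = 23.060548 kcal/mol,
R = 1.987204×10⁻³ kcal·mol⁻¹·K⁻¹, T = 298.15 K default), so the eV-route
(tuning maps) and the kT/e-route (projection maps) through the same bilinear
form agree to machine precision — a tested invariant. Grids are
node-centered with inclusive boundaries: a 64 Å box at 0.5 Å spacing has
129 nodes per axis, 2,146,689 total. Maps produced by a true
Poisson–Boltzmann solver can be substituted through the OpenDX reader; the
projection machinery is identical either way. The charge sum is evaluated by
a chunked dense double loop — O(n·m) is exact, trivially testable, and fast
at the problem sizes here (a full default grid against a small environment
evaluates in seconds).

## Projection maps

The projection rule is the unweighted mean of the **8 nearest grid nodes**
by Euclidean distance (KD-tree search, verified against exhaustive search;
distance ties broken by node index). This is deliberately *not* trilinear
cell-corner interpolation — the two differ whenever a point sits near a
node — though trilinear is available as an option. Values are clipped to
±0.25 kT/e for rendering export, the conventional color range.

A numerical note: the pointwise error of the nearest-8 rule is first-order
in the spacing with a prefactor that oscillates with the point's fractional
position in the lattice (the neighbor centroid is offset from the point by
up to half a cell). Convergence is therefore quantified on an ensemble —
the mean relative error over 100 points at 5 Å from a unit charge — which
decreases monotonically with spacing (≈2.2% → 0.9% → 0.5% at
1.0/0.5/0.25 Å) and sits well under 2% at 0.25 Å.

Per-region summaries (mean/min/max/sign) are reported for the three
isoalloxazine rings (xylene, central/pyrazine, pyrimidine), the labeled
sites, and the composite N5/C4 and C2/N3 faces that dominate tuning.

## Tuning maps and gap estimators

The frozen-density first-order model: given per-atom state difference
charges Δqᵢ (excited minus ground, zero-sum because excitation conserves
charge), a probe charge q at surface point p shifts the state's vertical
excitation energy by

    Δε(p) = k_C · q · Σᵢ Δqᵢ / |p − rᵢ|      [eV]

**Sign convention (the most error-prone contract): positive = blue-shift,
negative = red-shift.** The same form contracted with a protein potential φ
(kT/e) sampled at the atoms gives the environment-induced shift
ΔE = Σᵢ φᵢ·Δqᵢ·kT(eV) with kT(298.15 K) = 0.025693 eV, and the gap shift
Δ(gap) = ΔE_T − ΔE_S1 (positive = widening). The gap report combines the
S1 map's maximum red-shift with the Tn map's maximum blue-shift into a
combined tuning capacity; when either side is missing the report is flagged
degenerate and only the available extremum contributes.

This first-order model replaces per-probe excited-state calculations: maps
built from the packaged synthetic difference charges are **qualitative**
(correct sign structure and 0.01–0.05 eV magnitude scale at a +0.1 e probe
and k = 2, but not quantitative per-point values, which require the
quantum-chemical state densities). User-supplied difference charges from any
electronic-structure calculation plug into the same machinery.

## ASEC environments

An averaged electrostatic configuration merges N trajectory snapshots into
one point-charge cloud with every charge scaled by 1/N, so the merged
potential equals the frame-averaged potential at every external point
(tested to 10⁻⁹). Frames are extracted at absolute times k·interval
(nearest stored frame, earlier frame on ties); the default protocol is 100
frames at 50 ps. Lennard-Jones records are optionally carried as ε/N with σ
unchanged — this reproduces the frame-averaged dispersion sum, but since
the original averaging convention for LJ terms is not uniquely defined, an
unscaled mode is provided too.

QM/MM boundary handling zeroes MM charges near the link atom and splits
their total equally among recipient atoms, conserving global charge to
10⁻¹². A bond-topology helper derives a deterministic spec: atoms within 2
bonds of the link-atom host are zeroed, atoms exactly 3 bonds away receive.

Convergence of the iterative refine-and-resample loop uses a window-spread
rule: converged when the last 4 excitation energies span ≤ 0.02 eV
(max − min, matching "within … of one another" literally rather than a
successive-difference rule). The loop driver takes a pluggable energy
callback; synthetic energy sequences exercise the logic.

## Flexibility analysis

Frames are superposed onto the iterated mean structure (Kabsch SVD on the
Cα selection, two mean-refinement passes; collinear selections are
rejected), then per-residue Cα RMSF = √⟨|x − ⟨x⟩|²⟩ is computed, min–max
normalized to [0, 1] (constant profiles map to zero and are flagged),
written as PDB B-factors, and thresholded: residues strictly above the mean
normalized value are "flexible". Active-site residues are those with any
heavy atom within 4.0 Å (inclusive) of a chromophore heavy atom — inclusive
because the boundary convention only matters for atoms exactly on the
cutoff.

For isotropic per-axis noise σ the expected RMSF is σ√3. Rigid-body fitting
removes 6 degrees of freedom from the fit coordinates, deflating RMSF by
roughly √(1 − 2/N_Cα); the recovery checks therefore run at protein scale
(50 residues, a desk-scale stand-in for a ~110-residue LOV domain), where
the deflation is ≈2% and σ√3 is recovered within 5% from 12,000 frames
(within 15% at 500 frames). MDAnalysis serves as an independent RMSF oracle
in the test suite.

## Interpolation paths

Reaction paths between two optimized geometries are straight lines in
Cartesian coordinates: G_t = A + t·(B−A)/(n−1) over n interpolated points,
continued by the same step beyond both ends. Defaults are 15 interpolation
+ 3 extrapolation per side = 21 geometries (only the total is
protocol-fixed; the split is configurable and recorded in the output
manifest). Endpoints are reproduced bit-identically and spacing is uniform
to 10⁻⁹ Å. No re-superposition of B onto A is done by default — QM/MM
frames share the protein frame — but rigid pre-alignment is available for
free molecules. Energies along the path are left to external engines; the
package emits one XYZ per geometry plus a manifest.

## Synthetic data

The generator module supplies every fixture:

* **Toy flavin** — a planar fused tricycle (17 heavy atoms, idealized 1.4 Å
  ring bonds) with the canonical isoalloxazine sites (N1, C2, N3, C4, C4a,
  N5, N10, plus carbonyl O2/O4 and an N10 methyl) and ring labels
  xylene/central/pyrimidine. It has the right topology, labels and size for
  the map machinery, not a real flavin geometry.
* **Difference charges** — hand-chosen zero-sum sets: the S1 set is negative
  along the lower (N5-side) edge of the central and pyrimidine rings
  (positive probe there → red-shift), the Tn set is dominated by +0.20 e on
  N5 (lone-pair depletion → blue-shift from a nearby positive probe).
  Magnitudes put map extrema at a +0.1 e probe in the 0.01–0.05 eV range.
* **Environments** — "LOV1-like": +0.5 e placed 3 Å below the N5/C4 face;
  "LOV2-like": −0.5 e there plus a diffuse −0.05 e × 8 shell 4 Å above and
  below the xylene ring; "neutral": empty.
* **Trajectories** — a deterministic helical mini-protein (N/CA/C/O per
  residue) plus independent per-frame Gaussian displacements with
  prescribed per-residue σ, optional global rigid jitter (off by default so
  fluctuation recovery can be tested independently of superposition), all
  seeded and byte-reproducible.

What passing tests on these fixtures show: the map, projection, averaging
and selection machinery is correct, conserves charge, respects the stated
sign conventions, and recovers prescribed statistical parameters. What they
do not show: quantitative agreement with any real LOV domain's maps or
fluctuations — that requires real structures, force-field sampling and
excited-state densities, which are exactly the inputs this package accepts
but does not compute.

## Known limitations

* First-order electrostatics only: no polarization, induction, or
  Franck–Condon effects.
* The uniform-dielectric screened-Coulomb field is a stand-in for a true
  Poisson–Boltzmann solve (no dielectric boundary, no ionic accessibility);
  external DX maps should be used when quantitative protein potentials
  matter.
* Solvent-excluded (Connolly) surfaces and triangulated meshes are not
  implemented; surfaces are pruned sphere unions.
* PQR parsing is whitespace-delimited (PB-solver convention), not
  fixed-width.
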