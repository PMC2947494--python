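# Methods

## Governing equation and units

memslab solves the linearized Poisson–Boltzmann equation on a regular
node-centered grid.  Internally everything is non-dimensionalized: lengths
in Å, charges in elementary charges, and the potential as φ = eψ/k_BT, so
the equation reads

    -∇·[ε(r) ∇φ] + κ̄²(r) φ = C ρ(r),      C = e²/(ε₀ k_BT) ≈ 7043 Å at 298.15 K

with ρ in e/Å³.  κ̄² is the *modified* screening coefficient
(e²/ε₀k_BT)·Σᵢ zᵢ²nᵢ — the solvent dielectric is folded in, so it is twice
the single-species Debye constant for a symmetric 1:1 electrolyte and is
applied only at ion-accessible nodes.  For 0.1 M 1:1 salt at 298.15 K in
ε = 80 water the implied Debye length is 9.71 Å.  Energies are accumulated
in k_BT and reported simultaneously in kJ/mol and kcal/mol (1 kcal = 4.184
kJ).  All constants come from scipy.constants; nothing is hard-coded
beyond the kcal/kJ factor.

## Coefficient maps

**Dielectric.**  A two-pass probe-carved molecular surface: pass 1 marks
nodes within (r_atom + r_probe) of any atom; pass 2 rolls probe spheres
over the structure (centers sampled on the inflated atom spheres at
`surface_sphere_density` points/Å², default 10, kept when not buried in any
other inflated sphere) and returns to solvent every candidate node covered
by an accessible probe.  Nodes inside a van-der-Waals sphere are never
carved.  For a single atom this reproduces the vdW sphere exactly, which
is what makes the Born comparisons clean.  Defaults: probe 1.4 Å (water).
No dielectric smoothing is applied — a smoothed surface would shift every
energy in the worked cases.  A one-pass inflated-vdW mode exists for fast
previews.

**Ion accessibility.**  Binary: 0 within (r_atom + r_ion) of any atom
(r_ion defaults to 2 Å, the counter-ion radius) or anywhere in the
retained protein region, 1 elsewhere.  The bulk κ̄² multiplies this
indicator at solve time, keeping ionic strength a solver parameter.  The
choice of binary (rather than spline-smoothed) accessibility is a
numerical design decision; it converges to the same continuum limit and
keeps the kappa map exactly re-usable across salt concentrations.

**Charges.**  Cubic B-spline spreading (4-node support per axis).  The
kernel is a partition of unity, so total charge is conserved to round-off,
and it reproduces linear functions, so the density centroid sits exactly
at the atom position.  Potentials at atom positions are interpolated with
the *same* kernel; this adjoint pairing makes the grid self-energy of a
charge identical across same-grid solves, so it cancels exactly in every
state difference the workflows compute.  Atoms within two nodes of a grid
boundary are a hard error (the focusing ladder must keep charge support
interior).

## Membrane insertion

The slab [z_bottom, z_bottom + thickness] is rewritten into the maps in a
fixed node order: (1) protein nodes are untouched — detected by dielectric
equality with ε_protein, or by a separately retained protein mask when
ε_protein equals the membrane dielectric (the equality test is degenerate
exactly in the common ε_p = ε_m = 2 parameterization); (2) non-protein
slab nodes outside the exclusion cylinder become membrane: head-group
dielectric within `headgroup_thickness` of either face (per leaflet,
symmetric), core dielectric between, and ion accessibility zeroed in both
(the slab derivation assumes ions cannot enter any part of the membrane);
(3) for membrane-potential runs, nodes *below* the slab with nonzero ion
accessibility form the inner solution space.  Channel-lumen water inside
the slab belongs to the outer space — inner space is defined by z alone,
never by cylinder membership.

The exclusion region is a frustum: the radius interpolates linearly in z
between the lower and upper exclusion radii.  (A two-cylinder split at
mid-slab would be the alternative convention; linear interpolation was
chosen as the smoother of the two and is fixed.)

Insertion is idempotent, preserves the protein-node set, and at V = 0
leaves total grid charge unchanged (property-tested).

## Transmembrane potential

With an inner bath held at V and the outer bath at 0, the linear equation
fails the inner asymptotic condition unless a constant source is added in
the inner space: κ̄²(φ − φ̄_in)θ(r), θ the inner-space indicator.  Moved to
the right-hand side this is a uniform effective density

    ρ_eff = κ̄² φ̄_in / C = 2 c N_A φ̄_in / 10²⁷  e/Å³   (1:1 salt, c in mol/L)

Far from the protein the solution then settles at φ̄_in below the membrane
and 0 above.  Boundary values come from the analytic 1-D profile of a bare
dielectric slab in symmetric electrolyte: exponential Debye decay in both
baths, linear across the ion-free slab, joined continuously with the flux
condition ε_w φ'(water side) = ε_m φ'(membrane side).  The slab-profile
boundary uses the membrane core dielectric for the whole slab, ignoring
head groups.  By symmetry the mid-plane carries φ̄_in/2.  Because the
equation is linear the total potential separates into a protein field and
a membrane-potential field φ_mp; the gating workflow solves only the φ_mp
subproblem (protein charges zeroed, state-specific cavity retained) and
reports the pure cross term Σ qᵢ φ_mp(rᵢ).

**Valence sign convention.**  valence = −d(ΔG)/dV̄ with ΔG = G(state 2) −
G(state 1) in k_BT and V̄ the reduced inner-bath voltage: moving positive
charge from the inner bath (state 1) to the outer bath (state 2) gives a
positive valence equal to the fraction of the field traversed.  The sweep
uses 5 equally spaced voltages including 0 and ±V_max (default 50 mV) and
an ordinary least-squares slope; the LPB guarantees linearity, and the fit
residual is carried on the result as a diagnostic.

## Discretization and linear solve

Finite-volume 7-point stencil; face dielectrics are harmonic means of the
adjacent node values, which places an effective interface halfway between
nodes of different media.  The operator is symmetric positive definite;
Dirichlet boundaries are eliminated into the right-hand side.  Solves use
Jacobi-preconditioned conjugate gradients at a relative-residual tolerance
of 1e−6 (default; configurable), with the parent-level interpolant as the
initial guess inside a focusing ladder.  Non-convergence raises with the
achieved residual rather than returning silently.

Focusing supports up to three grids (two focusing levels); each child must
lie strictly inside its parent and takes trilinearly interpolated parent
values as boundaries.  Energies are always reported from the finest level.

When validating the membrane-potential solver against the analytic slab
profile we choose the grid spacing so the slab faces fall midway between
grid planes (h = thickness/19 at 65 nodes).  With harmonic-mean faces this
represents the dielectric jump at exactly the right position and the 3-D
solve tracks the analytic profile to ~0.003% of V; with arbitrary
alignment the interface is effectively displaced by up to h/2 and the
agreement degrades to O(h/L) of V, which is a discretization artifact, not
a solver defect.

## Workflows and cancellation

All three workflows are differences of solves on *identical* ladders:
identical grids, kernels, and surface construction per paired state, so
the spread-charge self-energy cancels exactly.  Protein solvation is
G(membrane) − G(bulk); ion solvation is G(protein+ion, membrane) −
G(protein, membrane) − G(ion, bulk) — nine solves on a three-level ladder
— with optional charges-off mode (cavity kept, partial charges zeroed) and
a residue-range charge mask for pore-helix-only style decompositions.

## Synthetic fixtures

The helix fixture is an ideal α-helix: 27 residues, 1.5 Å rise, 3.6
residues/turn, 2.3 Å Cα radius, z-aligned and centered; leucine throughout
except an arginine at position 14 whose +1 charge sits on an
outward-pointing guanidinium bead ~6.5 Å off the axis.  Residues are
coarse-grained to 5–6 pseudo-atoms with PARSE-like backbone partial
charges (N −0.40, Cα +0.40 with amide H folded in, C +0.55, O −0.55), so
each residue is net-neutral except the charged one.  The defaults mirror
the canonical single-TM-helix study conditions (42 Å slab at z = −21, 8 Å
ε = 80 head groups, ε_p = 5, ε_m = 2, 0.1 M salt, 200→100→50 Å ladder).

What the fixture does *not* emulate: an all-atom charge/radius set, real
side-chain packing, or backbone hydrogen-bond geometry.  Its solvation
energy (+38.8 kcal/mol charged, +11.0 neutral at 65³) therefore exercises
the full pipeline and reproduces the qualitative signature — a large
penalty dominated by the buried arginine — but is not expected to match
all-atom helix numbers, which depend on the parameter set used to build
the PQR.  Reproducing published channel values (KcsA ion transfer, mVDAC1
valence) additionally requires externally supplied PQR structures; the
packaged case2/case3 configs and the residue-mask machinery accept them
unchanged (drop the files into `inputs/` to enable the corresponding
end-to-end tests).

## Problem sizes

Analytic validations run at 33³–129³: the focused Born transfer uses a
160→80→40 Å ladder (1.9% from the closed form at 97³, errors 3.2% → 1.8% →
0.6% over 33/65/129), the Debye–Hückel check a 65³/80 Å box (≤1.2% at
10–25 Å), the slab consistency and traversal-valence checks 65³ boxes.
These sizes were chosen as the coarsest grids at which each comparison is
comfortably inside its analytic tolerance; the workflows accept any grid
dimension, and `convergence_scan` automates refinement studies.

## Known limitations

* Linear PB only; the nonlinear sinh term is out of scope (and the
  membrane-potential decomposition is only valid in the linear regime).
* Uniform protein dielectric; no smoothed or atom-specific variants.
* Flat, rigid slab: no curvature, bending relaxation, or per-leaflet
  asymmetry; no non-polar (surface-area) energy term.
* Water-filled cavities must be protected manually via the exclusion
  radii; there is no automatic cavity detection.
* The slab-profile boundary ignores head-group dielectrics, so very thick
  high-ε head groups slightly mis-specify the far-field clamp.
* Binary ion accessibility; no Stern-layer smoothing.
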