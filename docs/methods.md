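# Methods

## Scope and model

`porinflux` implements the trajectory analyses of computational
electrophysiology for wide, water-filled channels such as the trimeric
general-diffusion porins: counting complete ion permeation events across a
membrane slab, converting cumulative crossings into currents and an I-V
conductance, estimating ion selectivity as a cation/anion current ratio,
detecting the conformational and binding events that make up a
voltage-gating cascade, mapping hydrogen-bond persistence across the three
monomers of a trimer, and characterising the pore geometry and the charge
of its constriction zone.

Because atomistic trajectories of real porins are large and rarely
redistributable, the package carries its own input generator: an
overdamped Brownian-dynamics (BD) electrolyte whose every crossing and
binding event is logged exactly, so each analysis can be validated against
known ground truth rather than against another implementation of itself.

## Units

Angstrom, nanosecond, elementary charge, volt, picoampere, nanosiemens,
electronvolt throughout; all conversion factors live in
`porinflux.units`.  One crossing of one elementary charge per ns equals
160.2176634 pA.  Diffusion coefficients convert as
1e-5 cm^2/s = 100 A^2/ns.  Published diffusion-coefficient tables for
K+/Cl- are frequently printed as "cm^2/s" when 1e-5 cm^2/s is meant; the
package treats its shipped constants (K+ 1.96, Cl- 2.02) explicitly on the
1e-5 cm^2/s scale.

## Brownian-dynamics generator

Per ion and step, the Euler-Maruyama update is

    dr = (q e E D / kT) z_hat dt + sqrt(2 D dt) xi,

with `xi` standard normal per axis and `E = V/L_z` applied uniformly over
the whole box (matching the homogeneous-field setup used to impose a
transmembrane potential in MD).  Defaults model a desk-scale 1 M KCl
electrolyte at 310 K: a 50 x 50 x 100 A box with 150 K+ and 150 Cl-
(6e-4 ions/A^3 per species ~ 1 M), D = 196 / 202 A^2/ns, dt = 1 ps.  At
|V| = 1 V over 100 A the drift is ~0.07 A per step against a ~0.6 A
diffusive step, so the slab and pore boundaries are well resolved.

The membrane slab is impermeable except laterally inside one of the
configured pore cylinders; collisions are handled by specular reflection
(off a slab face from outside, off the cylinder wall from inside a pore).
This is the simplest scheme with the correct stationary density.  dt must
be small against the slab thickness; the defaults are.

Binding sites have capacity one.  A free ion entering the capture radius
of a free site is snapped to the site centre and frozen; each step it
escapes with probability `p_off`, re-appearing just outside the capture
radius (capture_radius + 0.5 A, random direction).  Snapping and the
outside re-entry point are deliberate: they make geometric site occupancy
(any ion within the cutoff) coincide exactly with the logged binding
intervals whenever the analysis cutoff equals the capture radius, which is
what the simulator-analysis closure checks exercise.  A release followed
by an immediate recapture appears as two logged intervals separated by one
frame; the occupancy analysis merges such gaps (1-frame tolerance), and
closure comparisons merge the log the same way.

Ground truth is logged at step resolution by a compartment automaton
independent of the analysis code path (same contract, separate
implementation), plus closed-form anchors: drift velocity `v = q e E D/kT`
and free-mode plane flux `rho A v`.  Identical configurations (including
the seed) give bit-identical output.

Not modelled: ion-ion electrostatics, explicit water/lipid, access
resistance (reservoir depletion), and any attempt at the absolute
conductance of a real porin.  Passing the closure and recovery tests
therefore demonstrates the correctness of the counting, regression and
geometry machinery on data obeying the model's assumptions — not that the
BD model reproduces atomistic trajectories.

## Crossing detection

Per ion, a three-compartment automaton (below / inside / above the slab)
with a hysteresis buffer (default 2 A) on each face: an exit commits only
past the far face plus the buffer, so boundary jitter cannot double-count.
Only below->inside->above (+1) and above->inside->below (-1) traversals
become events; a periodic jump in z (frame-to-frame |dz| > box_z/2)
toggles below<->above without an event and clears provenance.  A traversal
that enters and exits within one frame interval is timed as entering at
the previous frame.  Events are assigned to the monomer whose pore axis is
laterally nearest at the ion's first midplane passage (the assignment rule
is an implementation choice; per-monomer currents need one).

## Currents, conductance, selectivity

Within non-overlapping windows aligned to t = 0 (default 50 ns), the
crossing rate is the least-squares slope of the cumulative net-crossing
step function versus time, evaluated on a dense uniform sampling (201
points/window); current = rate x charge x 160.2176634 pA.  Note the LS
slope of a staircase differs from the endpoint difference quotient by up
to ~1 % depending on event phase within the window.

Conductance is the unweighted least-squares slope of total current versus
voltage, with the V = 0 point included at its measured (near-zero)
current; the intercept is kept as a diagnostic.  The corrected conductance
rescales each species' currents by D_experimental/D_simulated before the
fit.  Selectivity is |I_cation|/|I_anion| per monomer, reported as mean
and population standard deviation over the three monomers (three fixed
monomers are the whole population; switchable).

Diffusion coefficients come from the Einstein relation at zero field:
coordinates are unwrapped by minimum-image frame differences, the MSD is
averaged over ions and time origins, and D = slope/6 over a lag window
(default 10-50 % of the maximum lag).  Lag points are weighted by their
inverse standard error — the MSD at lag L rests on roughly (n-L)/L
independent segments, so long lags are much noisier.  For synthetic
overdamped walks there is no ballistic or caged regime, so the recovery
checks fit short lags (2-20 % of maximum), where the estimator variance
is lowest and the estimate is unbiased; for real MD data the longer
default window remains the safer choice.

## Conformation and gating

All structural measures superpose each frame onto frame 0 (the crystal
conformation) by Kabsch least squares on a caller-chosen selection — for
porins the beta-barrel C-alphas, which remain rigid under voltage.  RMSF
is per-atom RMS deviation from the time-mean position, averaged per
residue; segment RMSD compares against frame-0 coordinates; phi/psi use
the standard backbone definitions wrapped to (-180, 180]; PCA
diagonalises the covariance of the superposed selected coordinates.

Transition detection calls an event at the first frame whose deviation
from the running pre-event baseline exceeds a threshold (defaults: 60 deg
for angles by circular difference, 2 A for RMSD) and persists for at least
10 frames; thresholds and persistence are configurable because published
gating-event times are reported without an explicit criterion, and event
times from this module are not expected to match any particular
trajectory to the nanosecond.

Site occupancy marks a frame occupied when any ion of the filtered species
lies within the cutoff (default 3.5 A, inclusive) of any site atom by
minimum-image distance, attributes it to the nearest ion, and merges
stretches across 1-frame gaps.  Timelines stable-sort events by (time,
mechanistic kind order, label) and answer precedence queries per monomer.
Closure kinetics fit I(t) = a exp(-b t) by nonlinear least squares,
initialised from a log-linear fit of the positive samples;
non-positive or rising series are flagged as unfittable rather than
forced.

## Hydrogen-bond maps

A bond is present when the donor-acceptor distance is <= 3.5 A and, when
a donor hydrogen exists, the D-H...A angle deviates from linear by <= 30
deg (both inclusive; both configurable — these are the common geometric
criteria, since visualisation tools rarely print theirs).  Salt bridges
are screened by distance alone (angle waived with a warning when no
hydrogen is present).  The monomer-count map marks a bond present in a
monomer within a window when it holds in at least 50 % of the window's
frames — this presence rule is this package's rendering choice — and
reports counts 0-3 per window plus per-monomer persistence fractions.

## Pore profile and constriction zone

The pore radius at axial height z is the minimum over atoms within +/- 3 A
of z of (lateral distance from the axis minus the atom's van der Waals
radius), floored at zero; empty slabs give undefined (NaN) entries, not
errors.  The axis is fixed (default: principal axis of the chosen atoms);
porin barrels are straight, and no Monte-Carlo axis optimisation is
attempted — a documented simplification relative to full pore-tracing
tools.  Because the slab minimum forms a plateau of width ~ the slab
half-thickness, the narrowest point is reported at the axial position of
the contact atom achieving the minimum, not at a grid tie-break.

The constriction zone is the set of residues with any atom within 5 A
(a sphere) of the narrowest axis point; its net charge is the sum of
member formal charges under the pH-7 scheme (ASP/GLU -1 on a designated
side-chain atom, LYS/ARG +1, HIS and termini neutral — consistent with
side-chain-only charge accounting).  Pore-lining residues are those with
an atom within 3 A of the local pore surface; both cutoffs are
configurable, and charges are reported per monomer.  The screened-Coulomb
potential profile phi(z) = sum q_i exp(-r_i/lambda_D)/(4 pi eps0 eps_r
r_i) (eps_r default 80) is a qualitative stand-in for a Poisson-Boltzmann
calculation, normalised to the intracellular entrance grid point.

## Problem sizes used in the shipped checks

The recovery checks run at desk scale, chosen so each closed-form target
is resolved with comfortable statistics: conductance recovery uses one
species of 200 ions in the default box for 1e5 steps (100 ns) at V = -1,
0, +1 V over five seeds (expected ~1.7e4 crossings per voltage point);
selectivity uses 160 vs 40 ions with D 200 vs 100 A^2/ns (analytic ratio
8) for 2e4 steps over three seeds; diffusion recovery uses 1e5 ion-steps;
the simulator-analysis closures run with frame saving at every step so the
comparison can be exact.

## Known limitations

- The BD electrolyte is an ideal-gas ion model; currents scale linearly
  with density and field, so no saturation, screening or access-resistance
  effects appear.
- The crossing automaton assumes frames dense enough that an ion cannot
  cross slab-plus-buffer between consecutive frames undetected; with the
  generator defaults this holds by a wide margin.
- The radius profile under-resolves features sharper than the slab
  half-thickness, and the narrowest-point report assumes a single dominant
  contact.
- Formal-charge assignment is residue-table based; no pKa prediction.
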