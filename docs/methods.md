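# Methods

This note documents the estimators, the conventions and defaults behind
them, what the synthetic generators do and do not emulate, and the design
choices made where more than one reasonable definition exists. Units are
Å and ps internally; self-diffusion is reported in Å²/ns and viscosity in
mPa·s.

## Periodic geometry

Only orthorhombic cells are supported. Every pairwise quantity uses the
minimum-image convention with components in (−L/2, L/2]; unwrapping for
displacement statistics accumulates minimum-image frame-to-frame steps,
which is valid while no particle moves more than L/2 between frames.
Angles are computed as atan2(‖u×v‖, u·v), which is stable near 0° and
180°.

A caveat worth stating because two tests depend on it: a rigid rotation of
a *periodic* configuration is not a symmetry of the minimum-image metric —
rotation does not commute with lattice translations, so pairs that span
the box boundary change their image distances. Rigid-motion invariance
(of the SDF, ADF, hydrogen-bond detection) therefore holds exactly for
compact configurations whose relevant pairs do not span the boundary, and
that is how it is verified.

## Radial distribution function and coordination number

Histograms use half-open bins [lo, hi), values reported at bin centres,
default Δr = 0.05 Å. Site–site RDFs are intermolecular by default (pairs
sharing a molecule id are excluded) because the interesting correlations —
acid hydroxyl to chloride, acid to choline — span molecules. Cross-group
normalisation uses ρ = N_B/V and averages over A sites; when the two
selections are identical the self pair is dropped and ρ = (N−1)/V, which
makes an uncorrelated uniform system give exactly E[g] = 1 in both cases.

The coordination number is the integral CN(r) = 4πρ∫₀ʳ g(s)s²ds. On a
binned g this integral is evaluated *exactly* per bin (piecewise-constant
g times the analytic shell volume 4π/3(r₂³−r₁³)) rather than by a
trapezoid on g(s)s²: the exact form makes CN at every bin edge identical,
to round-off, to the mean neighbour count within that radius, which is
what the quantity means and what the oracle tests check. `cn_at(r)`
interpolates inside a bin with the same shell-volume rule.

First-shell detection smooths g with a centred moving average (window 5
bins, edge-padded) and takes the first local minimum after the first local
maximum that exceeds 1.05. The 0.05 margin keeps statistical ripple
around g ≈ 1 in a structureless fluid from registering as a shell; a
monotone or flat g yields an explicit "no shell" result (None) rather
than a number.

## ADF, CDFs, SDF

The ADF histograms the vertex angle of all (a, b, c) triples whose a–b and
b–c distances pass the cutoffs, weights each triple by 1/sin α (the
solid-angle measure — isotropically distributed triples then give a flat
density), skips and counts degenerate triples (sin α < 1e-12), and
normalises to unit trapezoid integral over bin centres.

Combined distribution functions are joint occurrence histograms over
matched instances. For the distance/angle CDF an instance is a (reference
molecule, partner atom) pair: the distance runs from a named reference
site to the partner, and the angle triple names reference sites with the
literal `"partner"` standing for the partner atom — this realises
combinations like "HA(acid)–Cl distance against C1–O1–Cl angle" with the
partner as the shared atom. For the distance/distance CDF an instance is
a (reference molecule, partner molecule) pair with one site pair per axis.
Values are normalised to unit maximum, TRAVIS display style, with raw
counts retained so marginals can be checked exactly. Duplicate site
labels within one molecule resolve to the first atom.

The SDF accumulates target positions in the molecule-fixed frame of three
anchor sites: origin at anchor 1, x-axis toward anchor 2, anchor 3 in the
xz half-plane with z ≥ 0 (Gram–Schmidt; the frame is right-handed).
Anchor triples with an opening angle under 5° are skipped and counted.
Densities are counts per voxel volume averaged over (frame, reference)
instances. The anchor frame is user-chosen configuration, not a fixed
convention.

## Hydrogen bonds

A bond is a donor–H···acceptor triple with minimum-image H···A distance
strictly below the cutoff and the D−H···A angle at the hydrogen inside a
closed window. The distance is measured hydrogen-to-acceptor (the ~2 Å
first RDF peak of the carboxyl hydrogen against chloride is an H···A
distance). Donor–hydrogen pairing is by shared molecule id; acceptors
must be in a different molecule. Presets: `cl_acceptor` (2 Å, 105–120°,
the bent chloride geometry), `o_acceptor` (2 Å, 150–180°, the near-linear
hydroxyl-oxygen geometry), `loose` (3.5 Å, 120–180°) for surveys. A
nominal "angle below 180°" constraint would exclude nothing, so the
window is always explicit.

Counts per frame are summarised by a nonlinear least-squares Gaussian fit
to the unit-bin integer histogram, initialised at the sample mean and
standard deviation; X̄ is reported as the average number of bonds together
with σ, the fit residual and σ/√n as a standard error (the published
uncertainty convention for such averages is ambiguous, so both scales are
available). A zero-variance series returns a degenerate-fit flag instead
of failing. Occupancy is the percentage of frames each unique (donor
molecule, acceptor atom) pair is bonded; equivalent acceptors count as
distinct pairs, and the presence matrix stores integer bond counts so the
per-frame total equals the row sum even if one donor molecule makes two
bonds to the same acceptor.

## Nonbonded energies and the stability factor

Group–group energies are literal pairwise sums over minimum-image
intermolecular pairs: no Ewald/PME, because the quantity of interest is
the defining sum, not a simulation engine's long-range machinery. An
optional cutoff (e.g. 12 Å) is available; the desk-scale default is none.
The Coulomb constant is fixed at k_e = 332.0636 kcal·Å·mol⁻¹·e⁻², the
standard MD convention. Lennard-Jones parameters combine by
Lorentz–Berthelot (R₀ arithmetic, D₀ geometric); the 12-6 form used puts
the pair minimum at exactly −D₀ᵢⱼ at r = R₀ᵢⱼ. Overlapping charged atoms
(r < 1e-6 Å) raise a singularity error naming the pair.

S = IE(HBA−HBD)/(IE(HBA−water)+IE(HBD−water)) is scale-free; a zero
denominator raises an explicit undefined-S error. The packaged
transcription of the published 353 K energy table carries a per-row
consistency flag: in two of the six compositions (both 700:300 rows) the
printed S cannot be recovered from the printed E_total values by the
defining ratio (0.8439 and 0.9079 recomputed against 0.878032 and
0.843856 printed), and one 300:700 row's E_vdw + E_Coul disagrees with
its printed E_total by ~7 kcal/mol. Those rows are flagged
`s_consistent=False` and excluded from worked-example checks; the four
self-consistent factors (0.107255, 0.327813, 0.36219, 0.680039) are
reproduced to 1e-4, which absorbs the printed rounding.

## Transport

All correlation estimators (MSD, VACF, VRD, stress ACF) average over
every time origin, normalising each lag by its origin count. The direct
O(N·lag) sums and the FFT evaluation are the same estimator algebraically;
`method='auto'` switches to FFT above 4096 samples, and the two paths are
tested to agree within 1e-9.

MSD uses unwrapped coordinates (per-molecule mass-weighted centres when a
`by_molecule_com` group is given). β(τ) is the centred finite difference
of log₁₀MSD against log₁₀τ, smoothed over 5 points; it is exact for a
pure power law. The diffusive window is the longest contiguous run with
|β−1| ≤ 0.1 spanning at least 10 lag points — the regime where the
Einstein limit applies; D = slope/6 over that window, converted to Å²/ns.
No window yields an explicit non-diffusive result rather than a number.

VACF zero crossings are located by sign change with linear interpolation;
the first is reported as a mean collision time, the second as the
velocity-randomization time. VRD normalises bond vectors to unit length
(zero-length vectors skip the whole molecule, counted) and fixes
VRD(0) = 1, making any overall prefactor irrelevant.

Green–Kubo viscosity averages the ACF of the three equivalent off-diagonal
stress components, integrates by trapezoid, and converts with
η = V/(k_BT)·∫C(t)dt using CODATA k_B, the declared stress unit (atm, bar,
Pa), Å³ volume and ps time. The plateau is the mean of the running
integral between the lag where |ACF| first falls below 2% of ACF(0) and
twice that lag: by then an exponential ACF has contributed ≥ 98% of its
integral, while stopping at ~2× the decay time keeps the random-walk
error of the tail out of the estimate. If the ACF never decays that far
a warning is raised and η(t) is returned without a plateau. Averaging
several independent series is supported by averaging their ACFs before
integration.

## Synthetic generators

All randomness flows through a counter-based Philox generator keyed by an
explicit integer seed; every output is bit-reproducible and carries its
ground-truth parameters in metadata. The generators emulate exactly the
features the estimators measure:

- *ideal gas*: i.i.d. uniform positions per frame — the g ≡ 1 null. The
  per-bin sampling error used in tests is binomial on the expected pair
  count, with a factor 2 on the variance for same-group counting (each
  unordered pair is seen twice).
- *planted triples*: donor–H–acceptor units at an exact distance/angle
  (optionally Gaussian-jittered), with collision-free placement.
- *Brownian/ballistic walkers*: Gaussian steps of per-axis variance
  2·D·dt (D given in Å²/ns), or straight-line motion; wrapped coordinates
  go into frames and the unwrapped truth into metadata so the unwrapping
  logic itself is testable.
- *OU velocity and stress series*: exact discretisation of the
  Ornstein–Uhlenbeck process, giving autocorrelations exp(−γt) and
  A·exp(−t/τc) with known Green–Kubo integral A·τc.
- *rigid rotor*: deterministic in-plane rotation, VRD(τ) = cos(ωτ).
- *toy DES mixture*: rigid coarse fragments — a six-site fatty acid with
  an exposed carboxyl O–H, a three-site choline with its hydroxyl, point
  chloride, three-site water — with partial charges loosely modelled on
  carboxylic-acid/choline/TIP3P values (net-neutral molecules, ±1 ions;
  the caprylic/lauric hydroxyl oxygens carry −0.6269/−0.6136 e). A chosen
  fraction of acids gets a chloride planted at 2.0 Å from its hydroxyl
  hydrogen at the bent 112.5° acceptor angle; water addition is emulated
  by solvating free chlorides with one near-linear O–H···Cl⁻ water each
  (at most one per free anion) plus randomly posed extra waters. Default
  intermolecular clearance is 3.2 Å, which keeps random Lennard-Jones
  contacts at the +1 kcal/mol scale and makes planted-contact counts
  exact under criteria tighter than the clearance. The exposed-hydrogen
  geometry guarantees a planted chloride clears every other site of its
  own donor by ≥ ~2.1 Å, so each planted contact is net-attractive
  (≈ −15 kcal/mol) and association measures scale with the planted
  fraction.

What the toy mixture does **not** emulate: thermal motion and exchange
(frames are static or jittered copies), force-field-accurate geometries
and charges, long-range dielectric response, finite-temperature H-bond
kinetics. Passing tests therefore demonstrate that the *estimators* are
correct on known ground truth and that the qualitative dilution trends
(first-peak height, occupancy, S all falling as planted contacts are
replaced by solvated anions) follow from the planted structure — they do
not reproduce any absolute simulated value from 50 ns force-field MD,
which is explicitly out of scope.

## Problem sizes

The shipped tests and the acceptance script run at desk scale, chosen so
each stochastic recovery has comfortable statistical margin: 10³–10⁵
samples for the structural χ²/isotropy checks, 200 walkers × 2000 frames
for diffusion (±10% on D), 10⁵-step OU series (±0.05 on the VACF point),
2×10⁵-step stress series (±10% on η with the plateau rule above), and
100-molecule mixtures for the dilution trends. The whole suite runs in
well under a minute of compute per module.

## Known limitations

- Orthorhombic cells only; no triclinic metric.
- Direct pairwise energy sums scale as O(N²) per frame pair — intended
  for the 10³–10⁴-atom scale, not production MD system sizes.
- The Gaussian count fit assumes a unimodal count distribution; strongly
  bimodal H-bond statistics would need a mixture model.
- First-shell detection reports the first smoothed local minimum; in a
  fluid with a genuine shoulder (no true minimum) the result depends on
  the smoothing window.
- PDB reading relies on MDAnalysis conventions for atom/residue naming;
  charges and LJ parameters never come from the PDB itself but from the
  side table.
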