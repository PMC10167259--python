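# destraj

Trajectory analysis for deep-eutectic-solvent (DES) simulations — the
structural, hydrogen-bond, energetic and transport properties used to judge
whether a hydrophobic eutectic pair (a hydrogen-bond acceptor such as
choline chloride, [Ch⁺][Cl⁻], and a fatty-acid hydrogen-bond donor such as
caprylic or lauric acid) stays associated when water is added.

The package is aimed at molecular-simulation practitioners who have
configurations or trajectories of such mixtures (extended XYZ or PDB plus a
site-parameter table) and want reproducible, tested implementations of the
standard analyses, together with synthetic generators that provide known
ground truth for every estimator.

## What it computes

**Structure** (`destraj.structure`)

- site–site radial distribution function g(r) with the running coordination
  number CN(r) = 4πρ∫₀ʳ g(s)s²ds, first-shell detection (first minimum of
  the smoothed g after its first peak) and CN at the first minimum;
- angular distribution function ADF(α) ∝ (1/sin α)·⟨δ(α − ∠(a,b,c))⟩ over
  site triples within distance cutoffs, normalised to unit integral;
- combined distribution functions: joint distance/angle and
  distance/distance histograms over matched site tuples, normalised to unit
  maximum (raw counts retained);
- spatial distribution function: 3D target density on a voxel grid in a
  molecule-fixed frame defined by three anchor sites.

**Hydrogen bonds** (`destraj.hbond`)

- geometric detection: H···A distance below a cutoff and D−H···A angle
  inside a window, with presets for the bent chloride acceptor
  (2 Å, 105–120°) and the near-linear hydroxyl-oxygen acceptor
  (2 Å, 150–180°);
- per-frame counts, a Gaussian fit
  F(X) = a/(σ√2π)·exp(−(X−X̄)²/2σ²) whose location X̄ is the average
  number of hydrogen bonds, and per-pair percent occupancy.

**Energetics** (`destraj.energetics`)

- group–group nonbonded energies by direct minimum-image sums,
  E_Coul = k_e Σ qᵢqⱼ/rᵢⱼ (k_e = 332.0636 kcal·Å/(mol·e²)) and the 12-6
  form E_vdW = Σ D₀ᵢⱼ[(R₀ᵢⱼ/r)¹² − 2(R₀ᵢⱼ/r)⁶] with Lorentz–Berthelot
  combination;
- the relative stability factor
  S = IE(HBA−HBD) / [IE(HBA−water) + IE(HBD−water)] — higher S means the
  eutectic pair resists disruption by water.

**Dynamics** (`destraj.dynamics`)

- mean-square displacement (all time origins, unwrapped coordinates), the
  local exponent β = d log₁₀MSD/d log₁₀τ, and the Einstein self-diffusion
  coefficient D = slope/6 on the diffusive window (|β−1| ≤ 0.1);
- normalised velocity autocorrelation with its first two zero crossings
  (mean collision and velocity-randomization times);
- bond-vector reorientation dynamics VRD(τ), normalised to VRD(0) = 1;
- Green–Kubo shear viscosity η = V/(k_BT)·∫⟨P_xy(0)P_xy(t)⟩dt from the
  three off-diagonal stress components, reported in mPa·s.

**Synthetic ground truth** (`destraj.synth`) — ideal-gas configurations,
planted donor–H···acceptor geometries, Brownian/ballistic particles,
Ornstein–Uhlenbeck velocity and stress series, rigid rotors, and a coarse
toy DES mixture with a controllable fraction of planted HA···Cl⁻ contacts
and chloride-solvating waters. Every generator is bit-reproducible from an
explicit seed and records its parameters in result metadata.

A config-driven pipeline (`destraj run config.yml`) chains the analyses and
writes one CSV/JSON per stage plus a manifest with all parameters, the seed
and input digests; re-running a manifest's config reproduces every output
byte for byte.

## Worked example

```python
import numpy as np
from destraj import synth, structure, hbond, energetics
from destraj.trajio import SimulationBox, SiteGroup

# a seeded coarse choline-chloride / caprylic-acid mixture in water
traj = synth.gen_toy_des_mixture(n_salt=100, n_fa=100, fa_type="CAP",
                                 box=SimulationBox([60.0] * 3),
                                 planted_fraction=0.5, n_water=150, seed=1)
top = traj.topology

# RDF between the carboxyl hydrogen of the acid and the chloride anion
res = structure.rdf(traj, top.select(site_label="HA", molecule_type="CAP"),
                    top.select(site_label="CL"), dr=0.03, r_max=10.0)
structure.first_minimum(res)
print(f"g(r) peak: {res.g.max():.1f} at r = {res.r[np.argmax(res.g)]:.2f} A")
print(f"first minimum r_min1 = {res.r_min1:.2f} A, CN = {res.cn_at_first_min:.3f}")

# hydrogen bonds under the bent chloride-acceptor criterion
crit = hbond.HBondCriterion("OA", "HA", "CL", 2.05, 105.0, 120.0)
series = hbond.hbond_count_series(traj, crit)
print(f"H-bonds in frame 0: {series.counts[0]}")

# relative stability factor S of the eutectic pair in water
hba = SiteGroup("hba", np.sort(np.concatenate(
    [top.select(molecule_type="CH"), top.select(molecule_type="CL")])))
hbd = SiteGroup("hbd", top.select(molecule_type="CAP"))
wat = SiteGroup("wat", top.select(molecule_type="WAT"))
rep = energetics.interaction_energy_report(
    traj, {"hba-hbd": (hba, hbd), "hba-water": (hba, wat),
           "hbd-water": (hbd, wat)})
e = {p.name: p.e_total for p in rep}
s = energetics.stability_factor(e["hba-hbd"], e["hba-water"], e["hbd-water"])
print(f"stability factor S = {s:.3f}")
```

prints

```
g(r) peak: 719.8 at r = 1.99 A
first minimum r_min1 = 2.08 A, CN = 0.500
H-bonds in frame 0: 50
stability factor S = 0.766
```

The g(r) maximum sits in the bin containing the planted 2.0 Å contact
distance; the coordination number at the first minimum is exactly the
planted contacts per acid (50/100); the strict bent-window criterion finds
exactly the 50 planted bonds; and S ≈ 0.77 quantifies how the salt–acid
attraction compares with what both components gain from water — it falls
monotonically as planted contacts are diluted and more chlorides are
solvated.

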