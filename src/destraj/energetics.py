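"""Group–group nonbonded interaction energies and the relative stability
factor of a deep eutectic solvent in water.

Energies are literal pairwise sums over minimum-image intermolecular
pairs (no Ewald/PME):

    E_Coul = k_e Σ q_i q_j / r_ij            k_e = 332.0636 kcal·Å/(mol·e²)
    E_vdW  = Σ D0_ij [ (R0_ij/r_ij)¹² − 2 (R0_ij/r_ij)⁶ ]

with Lorentz–Berthelot combination, D0_ij = √(D0_i·D0_j) and
R0_ij = (R0_i + R0_j)/2.  At r = R0_ij the Lennard-Jones term sits at its
minimum, −D0_ij.

The relative stability factor of an HBA/HBD eutectic pair in water is

    S = IE(HBA−HBD) / [ IE(HBA−water) + IE(HBD−water) ],

a scale-free ratio: large S means the acceptor–donor attraction dominates
what either component gains from water, i.e. the eutectic pair resists
disruption.  A transcription of the published 353 K energy table for the
caprylic/lauric-acid–choline-chloride systems ships with the package
(``load_reference_energies``) for worked-example checks; rows whose
printed totals are internally inconsistent are flagged, not used.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .trajio import (Frame, Topology, Trajectory, ValidationError,
                     as_indices, distance_matrix)

__all__ = [
    "K_COULOMB", "PairEnergy", "StabilityReport",
    "coulomb_energy", "vdw_energy", "interaction_energy_report",
    "stability_factor", "UndefinedStability", "SingularityError",
    "load_reference_energies", "stability_from_energies",
]

#: Coulomb constant e²/(4πε₀) in kcal·Å·mol⁻¹·e⁻² (standard MD convention).
K_COULOMB = 332.0636


class SingularityError(ValueError):
    """Two charged atoms (nearly) coincide."""


class UndefinedStability(ZeroDivisionError):
    """The stability-factor denominator is zero."""


@dataclass
class PairEnergy:
    """Time-averaged nonbonded energies for one group pair (kcal/mol)."""

    name: str
    e_vdw: float
    e_coul: float

    @property
    def e_total(self) -> float:
        return self.e_vdw + self.e_coul


def _pair_geometry(frame: Frame, topology: Topology, group_a, group_b,
                   cutoff: float | None):
    """Minimum-image distances and the intermolecular-pair mask."""
    idx_a = as_indices(group_a)
    idx_b = as_indices(group_b)
    if len(np.intersect1d(idx_a, idx_b)):
        raise ValidationError("groups must be disjoint at the atom level")
    d = distance_matrix(frame, idx_a, idx_b)
    mask = (topology.molecule_ids[idx_a][:, None]
            != topology.molecule_ids[idx_b][None, :])
    if cutoff is not None:
        mask &= d < cutoff
    return idx_a, idx_b, d, mask


def coulomb_energy(frame: Frame, topology: Topology, group_a, group_b,
                   cutoff: float | None = None) -> float:
    """Electrostatic A–B group energy in kcal/mol."""
    idx_a, idx_b, d, mask = _pair_geometry(frame, topology, group_a, group_b,
                                           cutoff)
    overlap = mask & (d < 1e-6)
    if np.any(overlap):
        i, j = np.argwhere(overlap)[0]
        raise SingularityError(
            f"atoms {idx_a[i]} and {idx_b[j]} overlap (r < 1e-6 Å)")
    qq = np.outer(topology.charges[idx_a], topology.charges[idx_b])
    with np.errstate(divide="ignore", invalid="ignore"):
        e = np.where(mask, qq / d, 0.0)
    return float(K_COULOMB * e.sum())


def vdw_energy(frame: Frame, topology: Topology, group_a, group_b,
               combining: str = "lb", cutoff: float | None = None) -> float:
    """Lennard-Jones A–B group energy in kcal/mol (Lorentz–Berthelot)."""
    if combining != "lb":
        raise ValueError(f"unknown combining rule {combining!r}")
    idx_a, idx_b, d, mask = _pair_geometry(frame, topology, group_a, group_b,
                                           cutoff)
    d0a, d0b = topology.lj_depth[idx_a], topology.lj_depth[idx_b]
    if np.any(d0a < 0) or np.any(d0b < 0):
        raise ValidationError("negative Lennard-Jones well depth D0")
    d0 = np.sqrt(np.outer(d0a, d0b))
    r0 = 0.5 * (topology.lj_rmin[idx_a][:, None]
                + topology.lj_rmin[idx_b][None, :])
    with np.errstate(divide="ignore", invalid="ignore"):
        x6 = (r0 / d) ** 6
        e = np.where(mask, d0 * (x6 * x6 - 2.0 * x6), 0.0)
    return float(e.sum())


def interaction_energy_report(traj: Trajectory, pairs: dict,
                              cutoff: float | None = None) -> list:
    """Time-averaged PairEnergy for each named (groupA, groupB) pair."""
    top = traj.topology
    out = []
    for name, (ga, gb) in pairs.items():
        ev = np.mean([vdw_energy(fr, top, ga, gb, cutoff=cutoff)
                      for fr in traj.frames])
        ec = np.mean([coulomb_energy(fr, top, ga, gb, cutoff=cutoff)
                      for fr in traj.frames])
        out.append(PairEnergy(name, float(ev), float(ec)))
    return out


def stability_factor(ie_hba_hbd: float, ie_hba_water: float,
                     ie_hbd_water: float) -> float:
    """S = IE(HBA−HBD) / (IE(HBA−water) + IE(HBD−water)).

    The ratio is scale-free; with all-attractive (negative) energies it is
    positive.  A zero denominator raises :class:`UndefinedStability`.
    """
    den = ie_hba_water + ie_hbd_water
    if den == 0:
        raise UndefinedStability("IE(HBA−water) + IE(HBD−water) is zero")
    return float(ie_hba_hbd / den)


@dataclass
class StabilityReport:
    """The three interaction energies (kcal/mol) and the resulting S."""

    ie_hba_hbd: float
    ie_hba_water: float
    ie_hbd_water: float

    @property
    def s(self) -> float:
        return stability_factor(self.ie_hba_hbd, self.ie_hba_water,
                                self.ie_hbd_water)


# --------------------------------------------------------------------------
# packaged reference table (published 353 K energies)
# --------------------------------------------------------------------------

def load_reference_energies() -> pd.DataFrame:
    """The packaged transcription of the published nonbonded-energy table.

    Columns: des (CCA/CLA), ratio (HBA:HBD), pair, e_vdw, e_coul, e_total,
    s_printed, s_consistent.  ``s_consistent`` is False where the printed
    S cannot be recovered from the printed E_total triple (both 700:300
    rows); those rows are excluded from worked-example checks.
    """
    with resources.files("destraj").joinpath(
            "data/table2_energies.csv").open() as fh:
        return pd.read_csv(fh)


def stability_from_energies(df: pd.DataFrame) -> pd.DataFrame:
    """Compute S per (des, ratio) from a table of E_total values.

    The input needs columns ``des, ratio, pair, e_total`` with pairs named
    ``salt_water`` (HBA–water), ``salt_fas`` (HBA–HBD) and ``fas_water``
    (HBD–water).
    """
    rows = []
    for (des, ratio), grp in df.groupby(["des", "ratio"], sort=True):
        e = grp.set_index("pair")["e_total"]
        rows.append({
            "des": des, "ratio": ratio,
            "s": stability_factor(e["salt_fas"], e["salt_water"],
                                  e["fas_water"]),
        })
    return pd.DataFrame(rows)
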