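"""Geometric hydrogen-bond detection, per-frame statistics and occupancy.

A donor–H···acceptor triple is a hydrogen bond when the minimum-image
H···A distance is below the cutoff and the D−H···A angle at the hydrogen
lies inside the configured window (endpoints inclusive).  The distance is
measured hydrogen-to-acceptor, matching the ~2 Å first RDF peak between
the fatty-acid hydroxyl hydrogen and the chloride anion.  Donor/acceptor
pairs within one molecule are never counted.

Presets reflect the two acceptor geometries of the choline-chloride /
fatty-acid systems: the chloride acceptor is bent (105–120°) while the
hydroxyl-oxygen acceptor is near-linear (150–180°), both at 2 Å; a loose
3.5 Å criterion is provided for survey work.

The per-frame count distribution is summarised by a Gaussian fit

    F(X) = a/(σ√(2π)) · exp(−(X − X̄)²/(2σ²)),

whose location X̄ is reported as the average number of hydrogen bonds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy.optimize import curve_fit

from .trajio import (Frame, Topology, Trajectory, ValidationError,
                     distance_matrix, minimum_image)

__all__ = [
    "HBondCriterion", "PRESETS", "HBond", "HBondSeries", "GaussianFit",
    "detect_hbonds", "hbond_count_series", "fit_gaussian_counts", "occupancy",
]


@dataclass(frozen=True)
class HBondCriterion:
    """Geometric criterion: site labels plus distance/angle windows."""

    donor: str
    hydrogen: str
    acceptor: str
    max_ha_distance: float            # Å, H···A
    angle_min: float = 0.0            # degrees, D−H···A window
    angle_max: float = 180.0

    def __post_init__(self):
        if self.max_ha_distance <= 0:
            raise ValidationError("distance cutoff must be positive")
        if not 0 <= self.angle_min < self.angle_max <= 180:
            raise ValidationError("need 0 <= angle_min < angle_max <= 180")


#: named criteria for the toy DES site labels (donor = FA hydroxyl).
PRESETS = {
    "cl_acceptor": HBondCriterion("OA", "HA", "CL", 2.0, 105.0, 120.0),
    "o_acceptor": HBondCriterion("OA", "HA", "O", 2.0, 150.0, 180.0),
    "loose": HBondCriterion("OA", "HA", "CL", 3.5, 120.0, 180.0),
}


class HBond(NamedTuple):
    donor: int
    hydrogen: int
    acceptor: int
    distance: float        # H···A, Å
    angle: float           # D−H···A, degrees


def detect_hbonds(frame: Frame, topology: Topology,
                  criterion: HBondCriterion) -> list:
    """All hydrogen bonds in one frame under the criterion.

    Donor–hydrogen pairs are formed within each molecule; acceptors must
    belong to a different molecule.
    """
    box = frame.box
    if criterion.max_ha_distance > float(np.min(box.lengths)) / 2 + 1e-9:
        raise ValidationError("distance cutoff exceeds half the box")
    d_idx = topology.select(site_label=criterion.donor)
    h_idx = topology.select(site_label=criterion.hydrogen)
    a_idx = topology.select(site_label=criterion.acceptor)
    out: list[HBond] = []
    if not (len(d_idx) and len(h_idx) and len(a_idx)):
        return out
    mids = topology.molecule_ids
    # donor-H pairing: same molecule
    pairs = [(d, h) for d in d_idx for h in h_idx if mids[d] == mids[h]]
    if not pairs:
        return out
    pos = frame.positions
    for d, h in pairs:
        dvec = minimum_image(pos[a_idx] - pos[h], box)
        dist = np.sqrt((dvec ** 2).sum(-1))
        cand = np.nonzero((dist < criterion.max_ha_distance)
                          & (mids[a_idx] != mids[h]))[0]
        if len(cand) == 0:
            continue
        u = minimum_image(pos[d] - pos[h], box)
        v = dvec[cand]
        cross = np.cross(np.broadcast_to(u, v.shape), v)
        ang = np.degrees(np.arctan2(np.linalg.norm(cross, axis=-1),
                                    v @ u))
        ok = (ang >= criterion.angle_min) & (ang <= criterion.angle_max)
        for k in np.nonzero(ok)[0]:
            out.append(HBond(int(d), int(h), int(a_idx[cand[k]]),
                             float(dist[cand[k]]), float(ang[k])))
    return out


@dataclass
class HBondSeries:
    """Per-frame counts plus the (donor molecule, acceptor atom) presence
    matrix used for occupancy.  ``presence`` values are per-frame bond
    counts for the pair, so each frame's total equals the row sum."""

    counts: np.ndarray                       # per-frame ints
    pairs: list                              # (donor_mol, acceptor_atom)
    presence: np.ndarray                     # (n_pairs, n_frames) ints
    criterion: HBondCriterion

    @property
    def n_frames(self) -> int:
        return len(self.counts)


def hbond_count_series(traj: Trajectory,
                       criterion: HBondCriterion) -> HBondSeries:
    """Detect bonds in every frame and assemble counts + presence matrix."""
    top = traj.topology
    per_pair: dict = {}
    counts = np.zeros(len(traj.frames), dtype=int)
    for k, frame in enumerate(traj.frames):
        bonds = detect_hbonds(frame, top, criterion)
        counts[k] = len(bonds)
        for b in bonds:
            key = (int(top.molecule_ids[b.donor]), b.acceptor)
            per_pair.setdefault(key, np.zeros(len(traj.frames), dtype=int))
            per_pair[key][k] += 1
    pairs = sorted(per_pair)
    presence = (np.array([per_pair[p] for p in pairs])
                if pairs else np.zeros((0, len(traj.frames)), dtype=int))
    return HBondSeries(counts, pairs, presence, criterion)


@dataclass
class GaussianFit:
    """Parameters of the Gaussian fitted to the per-frame count histogram."""

    a: float
    mean: float                 # X̄: the average number of hydrogen bonds
    sigma: float
    residual: float             # sum of squared fit residuals
    stderr: float               # σ/√n_frames
    degenerate: bool = False


def _gauss(x, a, mean, sigma):
    return a / (sigma * np.sqrt(2 * np.pi)) * np.exp(
        -((x - mean) ** 2) / (2 * sigma ** 2))


def fit_gaussian_counts(series: HBondSeries | np.ndarray,
                        min_frames: int = 30) -> GaussianFit:
    """Nonlinear least-squares Gaussian fit to the histogram of per-frame
    counts (unit-width integer bins), initialised at the sample mean/std.

    A constant series yields a degenerate-fit signal (σ → 0 flag) instead
    of an error.
    """
    counts = series.counts if isinstance(series, HBondSeries) else \
        np.asarray(series)
    n = len(counts)
    if n < min_frames:
        raise ValidationError(f"need at least {min_frames} frames, got {n}")
    mean = float(np.mean(counts))
    std = float(np.std(counts))
    if std == 0:
        return GaussianFit(a=float(n), mean=mean, sigma=0.0, residual=0.0,
                           stderr=0.0, degenerate=True)
    lo, hi = int(np.min(counts)), int(np.max(counts))
    edges = np.arange(lo, hi + 2) - 0.5
    hist, _ = np.histogram(counts, bins=edges)
    centres = np.arange(lo, hi + 1, dtype=float)
    popt, _ = curve_fit(_gauss, centres, hist, p0=[float(n), mean, std],
                        maxfev=10000)
    a, mu, sigma = popt
    sigma = abs(sigma)
    resid = float(np.sum((hist - _gauss(centres, a, mu, sigma)) ** 2))
    return GaussianFit(float(a), float(mu), float(sigma), resid,
                       sigma / np.sqrt(n))


def occupancy(series: HBondSeries):
    """Percent of frames each unique (donor molecule, acceptor atom) pair
    is bonded, sorted descending.  Returns a list of ((donor_mol,
    acceptor_atom), percent) tuples."""
    if series.presence.size == 0:
        return []
    pct = 100.0 * np.mean(series.presence > 0, axis=1)
    order = np.argsort(-pct, kind="stable")
    return [(series.pairs[i], float(pct[i])) for i in order]
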