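"""Synthetic configurations, trajectories and stationary series with known
ground truth.

Every generator takes an explicit integer seed and drives a counter-based
Philox bit generator, so outputs are bit-reproducible.  Ground-truth
parameters are attached to the returned object's ``meta`` dict so recovery
tests are self-describing.

The toy deep-eutectic-solvent mixture emulates the choline-chloride /
fatty-acid systems under study: coarse rigid molecules with labelled
donor/acceptor sites (FA carboxyl OA–HA, choline hydroxyl O–HA, chloride,
water) and a controllable fraction of planted FA.HA···Cl⁻ contacts at the
hydrogen-bond geometry.  The molecules are rigid fragments, not
force-field-accurate species: the analyses only require labelled sites and
geometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajio import (Frame, SimulationBox, Topology, Trajectory,
                     ValidationError, minimum_image)

__all__ = [
    "rng_from_seed",
    "gen_ideal_gas",
    "gen_planted_geometry",
    "gen_brownian",
    "gen_ou_velocity",
    "gen_stress_series",
    "gen_rigid_rotor",
    "gen_toy_des_mixture",
    "StressSeries",
    "TOY_PARAMS",
    "PackingError",
]


class PackingError(RuntimeError):
    """Could not place molecules without overlap within the retry budget."""


def rng_from_seed(seed: int) -> np.random.Generator:
    """Counter-based Philox generator keyed by an explicit integer seed."""
    return np.random.Generator(np.random.Philox(key=int(seed)))


def _point_topology(n: int, label: str = "X", element: str = "C",
                    mtype: str = "OTHER") -> Topology:
    return Topology(
        site_labels=np.array([label] * n, dtype=object),
        elements=np.array([element] * n, dtype=object),
        molecule_ids=np.arange(n),
        molecule_types=np.array([mtype] * n, dtype=object),
        charges=np.zeros(n),
        lj_depth=np.zeros(n),
        lj_rmin=np.zeros(n),
    )


# --------------------------------------------------------------------------
# homogeneous fluid / null model
# --------------------------------------------------------------------------

def gen_ideal_gas(n_atoms: int, box: SimulationBox, n_frames: int,
                  seed: int, dt: float = 1.0) -> Trajectory:
    """Uncorrelated uniform positions each frame (Poisson gas, g(r) ≡ 1)."""
    if n_atoms < 2:
        raise ValidationError("ideal gas needs at least 2 atoms")
    if box.volume <= 0:
        raise ValidationError("zero-volume box")
    rng = rng_from_seed(seed)
    top = _point_topology(n_atoms)
    frames = [Frame(k * dt, rng.uniform(0, 1, (n_atoms, 3)) * box.lengths, box)
              for k in range(n_frames)]
    traj = Trajectory(frames, top)
    traj.meta.update(kind="ideal_gas", density=n_atoms / box.volume, seed=seed)
    return traj


# --------------------------------------------------------------------------
# planted donor–H–acceptor geometries
# --------------------------------------------------------------------------

def _random_unit(rng, n=None):
    v = rng.normal(size=(3,) if n is None else (n, 3))
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def _perpendicular(u, rng):
    """A random unit vector perpendicular to unit vector u."""
    a = _random_unit(rng)
    p = a - np.dot(a, u) * u
    nrm = np.linalg.norm(p)
    while nrm < 1e-8:                                   # pragma: no cover
        a = _random_unit(rng)
        p = a - np.dot(a, u) * u
        nrm = np.linalg.norm(p)
    return p / nrm


def gen_planted_geometry(distance: float, angle: float, count: int,
                         box: SimulationBox, jitter: float = 0.0,
                         seed: int = 0, n_decoys: int = 0,
                         decoy_distance: float = 5.0, decoy_angle: float = 90.0,
                         donor_label: str = "OA", h_label: str = "HA",
                         acceptor_label: str = "CL", dh_bond: float = 1.0,
                         min_sep: float = 2.5, max_tries: int = 200):
    """Place ``count`` D–H···A triples with H···A distance ``distance`` (Å,
    Gaussian-jittered by ``jitter``) and D−H···A angle ``angle`` (deg),
    plus optional decoy triples at a different geometry.

    Returns (Frame, Topology).  The donor and hydrogen share a molecule;
    each acceptor is its own molecule.
    """
    if distance <= 0:
        raise ValidationError("distance must be positive")
    if not 0 < angle < 180:
        raise ValidationError("angle must be in (0, 180)")
    rng = rng_from_seed(seed)
    placed: list[np.ndarray] = []
    coords, labels, mids, mtypes, elems = [], [], [], [], []
    mol = 0

    def _try_place(d_ha, theta_deg):
        """One candidate triple; returns (D, H, A) positions or None."""
        h = rng.uniform(0, 1, 3) * box.lengths
        u = _random_unit(rng)                       # H -> A direction
        a = h + d_ha * u
        theta = np.radians(theta_deg)
        v = np.cos(theta) * u + np.sin(theta) * _perpendicular(u, rng)
        d = h + dh_bond * v                         # H -> D at the set angle
        new = np.array([d, h, a])
        if min_sep > 0 and placed:
            old = np.array(placed)
            dd = minimum_image(new[:, None, :] - old[None, :, :], box)
            if np.min(np.sqrt((dd ** 2).sum(-1))) < min_sep:
                return None
        return new

    def _add_triple(d_ha, theta_deg, acc_label):
        nonlocal mol
        for _ in range(max_tries):
            new = _try_place(d_ha, theta_deg)
            if new is not None:
                break
        else:
            raise PackingError("could not place triple without overlap")
        placed.extend(new)
        coords.extend(new)
        labels.extend([donor_label, h_label, acc_label])
        elems.extend(["O", "H", "CL"])
        mids.extend([mol, mol, mol + 1])
        mtypes.extend(["OTHER", "OTHER", "CL"])
        mol += 2

    for _ in range(count):
        d_ha = distance + (rng.normal(0, jitter) if jitter > 0 else 0.0)
        _add_triple(d_ha, angle, acceptor_label)
    for _ in range(n_decoys):
        _add_triple(decoy_distance, decoy_angle, acceptor_label)

    top = Topology(np.array(labels, dtype=object), np.array(elems, dtype=object),
                   np.array(mids), np.array(mtypes, dtype=object),
                   np.zeros(len(labels)), np.zeros(len(labels)),
                   np.zeros(len(labels)))
    frame = Frame(0.0, box.wrap(np.array(coords)), box)
    return frame, top


# --------------------------------------------------------------------------
# diffusing / ballistic particles
# --------------------------------------------------------------------------

def gen_brownian(n_particles: int, D: float, dt: float, n_frames: int,
                 box: SimulationBox, seed: int) -> Trajectory:
    """Independent Brownian walkers with self-diffusion coefficient ``D``
    in Å²/ns; per-axis step variance 2·D·dt (dt in ps).

    Wrapped coordinates go into the frames; the unwrapped ground truth is
    kept in ``traj.meta['unwrapped']``.
    """
    if D < 0:
        raise ValidationError("D must be non-negative")
    rng = rng_from_seed(seed)
    d_ps = D / 1000.0                                  # Å²/ps
    sigma = np.sqrt(2.0 * d_ps * dt)
    x0 = rng.uniform(0, 1, (n_particles, 3)) * box.lengths
    steps = (rng.normal(0, 1, (n_frames - 1, n_particles, 3)) * sigma
             if n_frames > 1 else np.zeros((0, n_particles, 3)))
    unwrapped = np.concatenate([x0[None], x0[None] + np.cumsum(steps, axis=0)])
    top = _point_topology(n_particles)
    frames = [Frame(k * dt, box.wrap(unwrapped[k]), box)
              for k in range(n_frames)]
    traj = Trajectory(frames, top)
    traj.meta.update(kind="brownian", D=D, seed=seed, unwrapped=unwrapped)
    return traj


def gen_ballistic(n_particles: int, speed: float, dt: float, n_frames: int,
                  box: SimulationBox, seed: int) -> Trajectory:
    """Straight-line motion at constant speed (Å/ps); MSD(τ) = v²τ²."""
    rng = rng_from_seed(seed)
    x0 = rng.uniform(0, 1, (n_particles, 3)) * box.lengths
    v = speed * _random_unit(rng, n_particles)
    t = np.arange(n_frames) * dt
    unwrapped = x0[None] + t[:, None, None] * v[None]
    top = _point_topology(n_particles)
    frames = [Frame(k * dt, box.wrap(unwrapped[k]), box, np.broadcast_to(
        v, (n_particles, 3)).copy()) for k in range(n_frames)]
    traj = Trajectory(frames, top)
    traj.meta.update(kind="ballistic", speed=speed, seed=seed,
                     unwrapped=unwrapped)
    return traj


# --------------------------------------------------------------------------
# stationary series (exact Ornstein–Uhlenbeck discretisation)
# --------------------------------------------------------------------------

def _ou_series(rng, variance: float, tau: float, dt: float, n: int,
               shape=()) -> np.ndarray:
    """Stationary OU process with Var = ``variance`` and autocorrelation
    exp(−t/τ), sampled exactly at spacing dt.  Leading axis is time."""
    rho = np.exp(-dt / tau)
    innov_sd = np.sqrt(variance * (1.0 - rho * rho))
    out = np.empty((n,) + shape)
    out[0] = rng.normal(0, np.sqrt(variance), shape)
    noise = rng.normal(0, innov_sd, (n - 1,) + shape) if n > 1 else None
    for k in range(1, n):
        out[k] = rho * out[k - 1] + noise[k - 1]
    return out


def gen_ou_velocity(gamma: float, kT_over_m: float, dt: float, n_frames: int,
                    seed: int, n_series: int = 1) -> np.ndarray:
    """Stationary velocity series whose normalized autocorrelation is
    exp(−gamma·t).  gamma in 1/ps, kT_over_m in Å²/ps² (the stationary
    per-axis variance).  Returns (n_frames, n_series, 3)."""
    if gamma <= 0:
        raise ValidationError("gamma must be positive")
    rng = rng_from_seed(seed)
    return _ou_series(rng, kT_over_m, 1.0 / gamma, dt, n_frames,
                      (n_series, 3))


@dataclass
class StressSeries:
    """Off-diagonal stress components (xy, xz, yz) on a uniform time grid."""

    data: np.ndarray            # (n_frames, 3)
    dt: float                   # ps
    meta: dict = field(default_factory=dict)

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.shape[0]) * self.dt


def gen_stress_series(A: float, tau_c: float, dt: float, n_frames: int,
                      seed: int) -> StressSeries:
    """Three independent stationary components with ACF A·exp(−t/tau_c)
    (OU construction).  ``A`` is the stress variance in (stress unit)²."""
    if A <= 0 or tau_c <= 0:
        raise ValidationError("A and tau_c must be positive")
    rng = rng_from_seed(seed)
    data = _ou_series(rng, A, tau_c, dt, n_frames, (3,))
    return StressSeries(data, dt, {"A": A, "tau_c": tau_c, "seed": seed})


def gen_rigid_rotor(omega: float, dt: float, n_frames: int) -> np.ndarray:
    """Unit vector rotating uniformly in a plane at ``omega`` rad/ps;
    deterministic.  Returns (n_frames, 3)."""
    if omega < 0:
        raise ValidationError("omega must be non-negative")
    t = np.arange(n_frames) * dt
    return np.stack([np.cos(omega * t), np.sin(omega * t),
                     np.zeros_like(t)], axis=1)


# --------------------------------------------------------------------------
# toy DES mixture
# --------------------------------------------------------------------------

#: toy parameter table keyed by (molecule_type, site_label):
#: (element, charge e, D0 kcal/mol, R0 Å).  Charges are loosely modelled on
#: carboxylic-acid / choline / TIP3P values; each molecule is net-neutral
#: except the ions (+1 choline, −1 chloride).
TOY_PARAMS = {
    ("CAP", "C1"): ("C", 0.75, 0.070, 4.00),
    ("CAP", "O1"): ("O", -0.55, 0.120, 3.40),
    ("CAP", "O2"): ("O", -0.10, 0.120, 3.40),
    ("CAP", "OA"): ("O", -0.6269, 0.152, 3.20),
    ("CAP", "HA"): ("H", 0.44, 0.046, 0.90),
    ("CAP", "CT"): ("C", 0.0869, 0.080, 4.20),
    ("LUA", "C1"): ("C", 0.75, 0.070, 4.00),
    ("LUA", "O1"): ("O", -0.55, 0.120, 3.40),
    ("LUA", "O2"): ("O", -0.10, 0.120, 3.40),
    ("LUA", "OA"): ("O", -0.6136, 0.152, 3.20),
    ("LUA", "HA"): ("H", 0.44, 0.046, 0.90),
    ("LUA", "CT"): ("C", 0.0736, 0.080, 4.60),
    ("CH", "C1"): ("C", 1.25, 0.080, 4.20),
    ("CH", "O"): ("O", -0.65, 0.152, 3.54),
    ("CH", "HA"): ("H", 0.40, 0.046, 0.90),
    ("CL", "CL"): ("CL", -1.0, 0.100, 3.60),
    ("WAT", "O"): ("O", -0.834, 0.152, 3.54),
    ("WAT", "H"): ("H", 0.417, 0.046, 0.90),
}

# Rigid local geometries: ordered (site_label, xyz Å) lists.  The hydroxyl
# hydrogens sit at the exposed end of each fragment so a planted acceptor
# at ~2 Å clears every other site of its donor molecule.
_TOY_GEOMETRY = {
    "FA": [                       # carboxyl head + tail bead
        ("OA", (-1.0, 0.0, 0.0)),
        ("HA", (0.0, 0.0, 0.0)),      # |HA−OA| = 1.0
        ("C1", (-2.30, 0.55, 0.0)),
        ("O1", (-2.90, 1.60, 0.0)),
        ("O2", (-3.30, -0.30, 0.0)),
        ("CT", (-4.50, 0.30, 0.0)),
    ],
    "CH": [
        ("O", (-1.0, 0.0, 0.0)),
        ("HA", (0.0, 0.0, 0.0)),      # |HA−O| = 1.0
        ("C1", (-2.40, 0.60, 0.0)),
    ],
    "CL": [("CL", (0.0, 0.0, 0.0))],
    "WAT": [
        ("O", (0.0, 0.0, 0.0)),
        ("H", (0.9572, 0.0, 0.0)),
        ("H", (-0.2400, 0.9266, 0.0)),
    ],
}


def _rotation_matrix(rng) -> np.ndarray:
    """Uniform random rotation (QR of a Gaussian matrix, det fixed to +1)."""
    m = rng.normal(size=(3, 3))
    q, r = np.linalg.qr(m)
    q *= np.sign(np.diag(r))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q


def gen_toy_des_mixture(n_salt: int, n_fa: int, fa_type: str = "CAP",
                        box: SimulationBox | None = None,
                        planted_fraction: float = 0.0, n_water: int = 0,
                        seed: int = 0, n_frames: int = 1,
                        frame_jitter: float = 0.0, dt: float = 1.0,
                        planted_distance: float = 2.0,
                        planted_angle: float = 112.5,
                        hydration_fraction: float = 1.0,
                        min_sep: float = 3.2, max_tries: int = 400):
    """Coarse choline-chloride / fatty-acid / water mixture with a planted
    fraction of FA.HA···Cl⁻ hydrogen-bond contacts.

    ``n_salt`` choline + chloride ion pairs and ``n_fa`` fatty acids
    (``fa_type`` CAP or LUA) are placed at random non-overlapping positions
    and orientations; ``round(planted_fraction · n_fa)`` chlorides are
    instead placed at ``planted_distance`` Å from an FA hydroxyl hydrogen
    with the donor–H···acceptor angle ``planted_angle`` (the geometry of
    the Cl⁻-acceptor hydrogen bond).  A ``hydration_fraction`` of the
    waters solvate chloride anions (near-linear O–H···Cl⁻ at 2 Å), the way
    added water strips the salt from the eutectic pair; the rest are
    placed at random poses.  Additional frames repeat the configuration
    with Gaussian positional jitter ``frame_jitter``.

    Returns a Trajectory (topology attached) with ground truth in ``meta``.
    """
    if n_salt < 0 or n_fa < 0 or n_water < 0:
        raise ValidationError("counts must be non-negative")
    if not 0.0 <= planted_fraction <= 1.0:
        raise ValidationError("planted_fraction must be in [0, 1]")
    fa_type = fa_type.upper()
    if fa_type not in ("CAP", "LUA"):
        raise ValidationError("fa_type must be CAP or LUA")
    if box is None:
        # loose liquid-like toy density: one molecule per (8 Å)³ cell
        n_mol = 2 * n_salt + n_fa + n_water
        box = SimulationBox([max(20.0, np.ceil((n_mol * 512.0) ** (1 / 3)))] * 3)
    rng = rng_from_seed(seed)
    n_planted = int(round(planted_fraction * n_fa))
    if n_planted > n_salt:
        raise ValidationError("not enough chlorides to plant the requested "
                              "fraction of contacts")

    coords: list[np.ndarray] = []
    labels, elems, mids, mtypes = [], [], [], []
    placed = np.zeros((0, 3))
    mol = 0

    def _place(kind, mtype):
        """Place one rigid molecule at a random pose clear of everything."""
        nonlocal placed, mol
        sites = [s for s, _ in _TOY_GEOMETRY[kind]]
        xyz = np.array([p for _, p in _TOY_GEOMETRY[kind]])
        xyz = xyz - xyz.mean(axis=0)
        for _ in range(max_tries):
            cand = xyz @ _rotation_matrix(rng).T + rng.uniform(0, 1, 3) * box.lengths
            if placed.shape[0]:
                dd = minimum_image(cand[:, None, :] - placed[None, :, :], box)
                if np.min(np.sqrt((dd ** 2).sum(-1))) < min_sep:
                    continue
            break
        else:
            raise PackingError(f"could not place {kind} after {max_tries} tries")
        placed = np.vstack([placed, cand])
        coords.extend(cand)
        labels.extend(sites)
        elems.extend(TOY_PARAMS[(mtype, s)][0] for s in sites)
        mids.extend([mol] * len(sites))
        mtypes.extend([mtype] * len(sites))
        mol += 1
        return cand, sites

    def _place_planted_cl(ha_pos, oa_pos, own_rows):
        """Chloride at the planted H-bond geometry relative to one FA.

        The candidate must clear every atom outside its own donor molecule
        by ``min_sep``; clearance from the donor's other sites (≥ ~2.1 Å)
        is guaranteed by the rigid carboxyl geometry.
        """
        nonlocal placed, mol
        w = oa_pos - ha_pos
        w = w / np.linalg.norm(w)                 # H -> donor direction
        theta = np.radians(planted_angle)
        others = np.delete(placed, own_rows, axis=0)
        for _ in range(max_tries):
            u = np.cos(theta) * w + np.sin(theta) * _perpendicular(w, rng)
            cand = (ha_pos + planted_distance * u)[None, :]
            dd = minimum_image(cand - others, box)
            if np.min(np.sqrt((dd ** 2).sum(-1))) >= min_sep:
                break
        else:
            raise PackingError("could not place planted chloride")
        placed = np.vstack([placed, cand])
        coords.extend(cand)
        labels.append("CL")
        elems.append("CL")
        mids.append(mol)
        mtypes.append("CL")
        mol += 1

    def _place_hydration_water(cl_pos, cl_row):
        """Rigid water donating a near-linear O–H···Cl⁻ contact at 2 Å."""
        nonlocal placed, mol
        others = np.delete(placed, [cl_row], axis=0)
        theta = np.radians(165.0)
        hoh = np.radians(104.5)
        for _ in range(max_tries):
            u = _random_unit(rng)
            h1 = cl_pos + 2.0 * u
            # O–H1 points back toward Cl at 165°
            v = np.cos(theta) * (-u) + np.sin(theta) * _perpendicular(u, rng)
            o = h1 + 0.9572 * v
            w2 = (np.cos(hoh) * (-v)
                  + np.sin(hoh) * _perpendicular(v, rng))
            h2 = o + 0.9572 * w2
            cand = np.array([o, h1, h2])
            dd = minimum_image(cand[:, None, :] - others[None, :, :], box)
            if np.min(np.sqrt((dd ** 2).sum(-1))) >= min_sep:
                break
        else:
            raise PackingError("could not place hydration water")
        placed = np.vstack([placed, cand])
        coords.extend(cand)
        labels.extend(["O", "H", "H"])
        elems.extend(["O", "H", "H"])
        mids.extend([mol] * 3)
        mtypes.extend(["WAT"] * 3)
        mol += 1

    # fatty acids first (planted chlorides hang off the first n_planted)
    n_fa_sites = len(_TOY_GEOMETRY["FA"])
    fa_sites_cache = []
    for k in range(n_fa):
        cand, sites = _place("FA", fa_type)
        fa_sites_cache.append((cand[sites.index("HA")],
                               cand[sites.index("OA")]))
    cl_rows: list[int] = []           # row of each chloride in `placed`
    for k in range(n_planted):
        ha_pos, oa_pos = fa_sites_cache[k]
        _place_planted_cl(ha_pos, oa_pos,
                          np.arange(k * n_fa_sites, (k + 1) * n_fa_sites))
        cl_rows.append(placed.shape[0] - 1)
    planted_cl_rows = list(cl_rows)
    for _ in range(n_salt - n_planted):
        _place("CL", "CL")
        cl_rows.append(placed.shape[0] - 1)
    for _ in range(n_salt):
        _place("CH", "CH")
    # at most one solvating water per free chloride (the planted ones are
    # engaged in the eutectic contact and too crowded to hydrate)
    free_cl = cl_rows[len(planted_cl_rows):]
    n_hydrated = min(int(round(hydration_fraction * n_water)), len(free_cl))
    for k in range(n_hydrated):
        _place_hydration_water(placed[free_cl[k]], free_cl[k])
    for _ in range(n_water - n_hydrated):
        _place("WAT", "WAT")

    labels_a = np.array(labels, dtype=object)
    mtypes_a = np.array(mtypes, dtype=object)
    charges = np.array([TOY_PARAMS[(m, s)][1] for m, s in zip(mtypes, labels)])
    d0 = np.array([TOY_PARAMS[(m, s)][2] for m, s in zip(mtypes, labels)])
    r0 = np.array([TOY_PARAMS[(m, s)][3] for m, s in zip(mtypes, labels)])
    top = Topology(labels_a, np.array(elems, dtype=object), np.array(mids),
                   mtypes_a, charges, d0, r0)
    base = box.wrap(np.array(coords))
    frames = []
    for k in range(n_frames):
        pos = base if (k == 0 or frame_jitter == 0) else box.wrap(
            base + rng.normal(0, frame_jitter, base.shape))
        frames.append(Frame(k * dt, pos, box))
    traj = Trajectory(frames, top)
    traj.meta.update(kind="toy_des_mixture", seed=seed, n_salt=n_salt,
                     n_fa=n_fa, n_water=n_water, fa_type=fa_type,
                     n_planted=n_planted, planted_distance=planted_distance,
                     planted_angle=planted_angle, n_hydrated=n_hydrated)
    return traj
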