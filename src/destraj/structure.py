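"""Structural correlation functions: site–site radial distribution
functions with coordination numbers, angular distribution functions,
combined (2D) distribution functions, and spatial distribution functions
on a molecule-fixed voxel grid.

Conventions
-----------
* Histograms use half-open bins [lo, hi); values are reported at bin
  centres.
* Site–site RDFs are intermolecular by default (pairs within one molecule
  are excluded).
* The coordination number CN = 4πρ∫₀^r g(s)s²ds is evaluated exactly per
  bin (piecewise-constant g × the analytic shell volume), which makes it
  identical to the mean neighbour count within each bin edge — the
  quantity the integral represents.
* Angles are computed with atan2(‖u×v‖, u·v) for stability near 0°/180°.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajio import (SiteGroup, Trajectory, ValidationError, as_indices,
                     distance_matrix, minimum_image)

__all__ = [
    "RDFResult", "ADFResult", "CDF2DResult", "SDFGrid",
    "rdf", "first_minimum", "adf", "cdf_dist_angle", "cdf_dist_dist", "sdf",
]


def _angles_at(b, a, c, box):
    """Angle(s) at vertex b between points a and c, in degrees."""
    u = minimum_image(a - b, box)
    v = minimum_image(c - b, box)
    cross = np.cross(u, v)
    dot = np.sum(u * v, axis=-1)
    return np.degrees(np.arctan2(np.linalg.norm(cross, axis=-1), dot))


# --------------------------------------------------------------------------
# RDF + coordination number
# --------------------------------------------------------------------------

@dataclass
class RDFResult:
    """Binned pair distribution g(r) with its running coordination number.

    ``cn[i]`` is the mean number of B neighbours of an A site within
    ``r_edges[i+1]``; ``r_min1``/``cn_at_first_min`` are populated by
    :func:`first_minimum`.
    """

    r: np.ndarray               # bin centres, Å
    g: np.ndarray
    cn: np.ndarray              # cumulative CN at the right bin edges
    r_edges: np.ndarray
    rho: float                  # number density of the B group, Å⁻³
    meta: dict = field(default_factory=dict)
    r_min1: float | None = None
    cn_at_first_min: float | None = None

    def cn_at(self, r: float) -> float:
        """CN at radius r: exact at bin edges, shell-volume interpolation
        inside a bin (consistent with piecewise-constant g)."""
        edges = self.r_edges
        if r <= edges[0]:
            return 0.0
        i = min(np.searchsorted(edges, r, side="right") - 1, len(self.g) - 1)
        base = self.cn[i - 1] if i > 0 else 0.0
        lo = edges[i]
        hi = min(r, edges[i + 1])
        return float(base + self.rho * self.g[i]
                     * 4.0 * np.pi / 3.0 * (hi ** 3 - lo ** 3))


def rdf(traj: Trajectory, group_a, group_b, dr: float = 0.05,
        r_max: float | None = None,
        exclude_intramolecular: bool = True) -> RDFResult:
    """Site–site radial distribution function between two selections.

    Normalised so an uncorrelated homogeneous system gives g ≡ 1: the
    cross-group density ρ is N_B/V; when the two selections are identical
    the self pair is excluded and ρ = (N_B−1)/V.
    """
    idx_a = as_indices(group_a)
    idx_b = as_indices(group_b)
    if len(idx_a) == 0 or len(idx_b) == 0:
        raise ValidationError("RDF groups must be non-empty")
    box = traj.frames[0].box
    half = float(np.min(box.lengths)) / 2.0
    if r_max is None:
        r_max = half
    if r_max > half + 1e-9:
        raise ValidationError(f"r_max={r_max} exceeds half the box ({half})")
    n_bins = int(np.floor(r_max / dr))
    edges = np.arange(n_bins + 1) * dr
    top = traj.topology
    same_group = len(idx_a) == len(idx_b) and np.array_equal(
        np.sort(idx_a), np.sort(idx_b))

    counts = np.zeros(n_bins)
    for frame in traj.frames:
        d = distance_matrix(frame, idx_a, idx_b)
        mask = np.ones_like(d, dtype=bool)
        mask &= idx_a[:, None] != idx_b[None, :]
        if exclude_intramolecular:
            mask &= (top.molecule_ids[idx_a][:, None]
                     != top.molecule_ids[idx_b][None, :])
        h, _ = np.histogram(d[mask], bins=edges)
        counts += h

    n_frames = len(traj.frames)
    per_a = counts / (n_frames * len(idx_a))        # mean neighbours per bin
    volume = box.volume
    n_b_eff = len(idx_b) - 1 if same_group else len(idx_b)
    rho = n_b_eff / volume
    shell = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    g = per_a / (rho * shell)
    cn = np.cumsum(per_a)
    centres = 0.5 * (edges[1:] + edges[:-1])
    return RDFResult(centres, g, cn, edges, rho,
                     meta={"n_frames": n_frames, "n_a": len(idx_a),
                           "n_b": len(idx_b), "dr": dr, "r_max": r_max,
                           "exclude_intramolecular": exclude_intramolecular})


def _moving_average(y: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return y.copy()
    kernel = np.ones(window) / window
    # edge-padded so the smoothed curve has the same length
    pad = window // 2
    yp = np.pad(y, pad, mode="edge")
    out = np.convolve(yp, kernel, mode="same")[pad:pad + len(y)]
    return out


def first_minimum(result: RDFResult, smooth_window: int = 5,
                  min_height: float = 1.05):
    """First local minimum of the (smoothed) g(r) after its first peak.

    Returns ``r_min1`` and stores it with the coordination number at that
    radius on the result.  Returns None (a "no shell" signal) when g has
    no peak above ``min_height`` — the margin keeps statistical ripple
    around g ≈ 1 in a structureless fluid from registering as a shell.
    """
    gs = _moving_average(result.g, smooth_window)
    n = len(gs)
    peak = None
    for i in range(1, n - 1):
        if gs[i] > min_height and gs[i] >= gs[i - 1] and gs[i] >= gs[i + 1]:
            peak = i
            break
    if peak is None:
        result.r_min1 = None
        result.cn_at_first_min = None
        return None
    for i in range(peak + 1, n - 1):
        if gs[i] <= gs[i - 1] and gs[i] <= gs[i + 1] and gs[i] < gs[peak]:
            result.r_min1 = float(result.r[i])
            result.cn_at_first_min = float(result.cn[i])
            return result.r_min1
    result.r_min1 = None
    result.cn_at_first_min = None
    return None


# --------------------------------------------------------------------------
# ADF
# --------------------------------------------------------------------------

@dataclass
class ADFResult:
    """Angle distribution over (a, b, c) site triples, 1/sin-corrected and
    normalised to unit integral over α ∈ (0°, 180°)."""

    alpha: np.ndarray           # bin centres, degrees
    density: np.ndarray
    counts: np.ndarray          # raw (unweighted) triple counts per bin
    edges: np.ndarray
    n_skipped: int
    meta: dict = field(default_factory=dict)


def adf(traj: Trajectory, group_a, group_b, group_c,
        cutoff_ab: float, cutoff_bc: float,
        bin_width: float = 1.0) -> ADFResult:
    """Distribution of the angle at B over all (A, B, C) triples whose
    A–B and B–C distances pass the cutoffs, weighted by 1/sin α and
    normalised to unit integral.  Degenerate triples (coincident points)
    are skipped and counted."""
    idx_a = as_indices(group_a)
    idx_b = as_indices(group_b)
    idx_c = as_indices(group_c)
    box = traj.frames[0].box
    half = float(np.min(box.lengths)) / 2.0
    if max(cutoff_ab, cutoff_bc) > half + 1e-9:
        raise ValidationError("cutoffs must not exceed half the box")
    edges = np.arange(0.0, 180.0 + bin_width / 2, bin_width)
    weighted = np.zeros(len(edges) - 1)
    counts = np.zeros(len(edges) - 1)
    n_skipped = 0
    for frame in traj.frames:
        pos = frame.positions
        d_ab = distance_matrix(frame, idx_b, idx_a)
        d_cb = distance_matrix(frame, idx_b, idx_c)
        for kb, b in enumerate(idx_b):
            near_a = idx_a[(d_ab[kb] < cutoff_ab) & (idx_a != b)]
            near_c = idx_c[(d_cb[kb] < cutoff_bc) & (idx_c != b)]
            if len(near_a) == 0 or len(near_c) == 0:
                continue
            aa, cc = np.meshgrid(near_a, near_c, indexing="ij")
            keep = aa != cc
            aa, cc = aa[keep], cc[keep]
            if len(aa) == 0:
                continue
            ang = _angles_at(pos[b], pos[aa], pos[cc], box)
            s = np.sin(np.radians(ang))
            good = s > 1e-12
            n_skipped += int(np.sum(~good))
            h, _ = np.histogram(ang[good], bins=edges, weights=1.0 / s[good])
            weighted += h
            hc, _ = np.histogram(ang[good], bins=edges)
            counts += hc
    centres = 0.5 * (edges[1:] + edges[:-1])
    integral = np.trapezoid(weighted, centres)
    density = weighted / integral if integral > 0 else weighted
    return ADFResult(centres, density, counts, edges, n_skipped,
                     meta={"cutoff_ab": cutoff_ab, "cutoff_bc": cutoff_bc,
                           "bin_width": bin_width})


# --------------------------------------------------------------------------
# combined distribution functions
# --------------------------------------------------------------------------

@dataclass
class CDF2DResult:
    """Joint 2D occurrence histogram normalised to unit maximum; raw
    counts retained in ``counts``."""

    edges1: np.ndarray
    edges2: np.ndarray
    values: np.ndarray          # normalised to [0, 1]
    counts: np.ndarray
    axis1_label: str
    axis2_label: str
    meta: dict = field(default_factory=dict)
    empty: bool = False


def _ref_molecules(top, ref_type):
    """List of {site_label: atom_index} dicts, one per reference molecule
    (first atom wins on duplicate labels within a molecule)."""
    out = []
    for mid in np.unique(top.molecule_ids[top.molecule_types == ref_type]):
        sel = np.nonzero(top.molecule_ids == mid)[0]
        sites = {}
        for k in sel:
            sites.setdefault(str(top.site_labels[k]), int(k))
        out.append(sites)
    return out


def _instance_geometry(traj, ref_type, partner, ref_sites_needed):
    """Yield, per frame, (ref site positions dict, partner positions)."""
    top = traj.topology
    mols = _ref_molecules(top, ref_type)
    missing = [s for s in ref_sites_needed
               if any(s not in m for m in mols)]
    if not mols:
        raise ValidationError(f"no molecules of type {ref_type!r}")
    if missing:
        raise ValidationError(
            f"reference molecules lack site label(s) {missing}")
    p_idx = as_indices(partner)
    for frame in traj.frames:
        yield frame, mols, frame.positions[p_idx]


def cdf_dist_angle(traj: Trajectory, ref_type: str, partner,
                   dist_site: str, angle_sites: tuple,
                   d_edges: np.ndarray, a_edges: np.ndarray,
                   dist_partner: bool = True) -> CDF2DResult:
    """Joint distance/angle histogram over (reference molecule, partner
    atom) instances.

    The distance axis is |ref[dist_site] − partner|.  ``angle_sites`` is a
    triple of reference-molecule site labels, one of which may be the
    literal string ``"partner"``; the angle is taken at its middle member.
    Instances with both observables inside the bin ranges are counted.
    """
    d_edges = np.asarray(d_edges, float)
    a_edges = np.asarray(a_edges, float)
    needed = {dist_site} | {s for s in angle_sites if s != "partner"}
    counts = np.zeros((len(d_edges) - 1, len(a_edges) - 1))
    box = traj.frames[0].box
    for frame, mols, ppos in _instance_geometry(traj, ref_type, partner,
                                                needed):
        for sites in mols:
            anchor = frame.positions[sites[dist_site]]
            dvec = minimum_image(ppos - anchor, box)
            dist = np.sqrt((dvec ** 2).sum(-1))
            tri = []
            for s in angle_sites:
                tri.append(None if s == "partner"
                           else frame.positions[sites[s]])
            a_pt, b_pt, c_pt = tri
            ang = _angles_at(
                b_pt if b_pt is not None else ppos,
                np.broadcast_to(a_pt, ppos.shape) if a_pt is not None else ppos,
                np.broadcast_to(c_pt, ppos.shape) if c_pt is not None else ppos,
                box)
            h, _, _ = np.histogram2d(dist, ang, bins=[d_edges, a_edges])
            counts += h
    total = counts.max()
    empty = total == 0
    values = counts / total if not empty else counts
    return CDF2DResult(d_edges, a_edges, values, counts,
                       f"{ref_type}.{dist_site}–partner distance (Å)",
                       "angle (deg)", {"ref_type": ref_type}, empty)


def cdf_dist_dist(traj: Trajectory, ref_type: str, partner_type: str,
                  pair_a: tuple, pair_b: tuple,
                  edges_a: np.ndarray, edges_b: np.ndarray) -> CDF2DResult:
    """Joint histogram of two distances over (reference molecule, partner
    molecule) pairs; ``pair_a``/``pair_b`` are (ref site, partner site)
    label pairs.  Swapping the two specs transposes the result."""
    edges_a = np.asarray(edges_a, float)
    edges_b = np.asarray(edges_b, float)
    top = traj.topology
    refs = _ref_molecules(top, ref_type)
    partners = _ref_molecules(top, partner_type)
    if not refs or not partners:
        raise ValidationError("empty reference or partner selection")
    box = traj.frames[0].box
    counts = np.zeros((len(edges_a) - 1, len(edges_b) - 1))
    for frame in traj.frames:
        pos = frame.positions
        pa1 = np.array([pos[m[pair_a[0]]] for m in refs])
        pb1 = np.array([pos[m[pair_b[0]]] for m in refs])
        pa2 = np.array([pos[m[pair_a[1]]] for m in partners])
        pb2 = np.array([pos[m[pair_b[1]]] for m in partners])
        da = np.sqrt((minimum_image(pa2[None] - pa1[:, None], box) ** 2).sum(-1))
        db = np.sqrt((minimum_image(pb2[None] - pb1[:, None], box) ** 2).sum(-1))
        h, _, _ = np.histogram2d(da.ravel(), db.ravel(),
                                 bins=[edges_a, edges_b])
        counts += h
    total = counts.max()
    empty = total == 0
    values = counts / total if not empty else counts
    return CDF2DResult(edges_a, edges_b, values, counts,
                       f"{ref_type}.{pair_a[0]}–{partner_type}.{pair_a[1]} (Å)",
                       f"{ref_type}.{pair_b[0]}–{partner_type}.{pair_b[1]} (Å)",
                       {"ref_type": ref_type, "partner_type": partner_type},
                       empty)


# --------------------------------------------------------------------------
# SDF
# --------------------------------------------------------------------------

@dataclass
class SDFGrid:
    """Mean target number density (Å⁻³) on a voxel grid in the
    molecule-fixed frame of the anchor triple: origin at anchor 1, x-axis
    toward anchor 2, anchor 3 in the xz half-plane (z ≥ 0)."""

    voxel: float
    extent: float
    density: np.ndarray         # (n, n, n)
    counts: np.ndarray
    anchors: tuple
    n_instances: int
    n_skipped: int
    meta: dict = field(default_factory=dict)

    @property
    def grid_centres(self) -> np.ndarray:
        n = self.density.shape[0]
        return -self.extent + (np.arange(n) + 0.5) * self.voxel


def sdf(traj: Trajectory, ref_type: str, anchors: tuple, target,
        voxel: float = 0.5, extent: float = 8.0,
        min_anchor_angle: float = 5.0) -> SDFGrid:
    """Spatial distribution of ``target`` atoms around reference molecules.

    Every (frame, reference molecule) instance defines a local frame from
    the three anchor sites; target positions (minimum image relative to
    anchor 1) falling inside the cube of half-width ``extent`` are binned.
    Instances with nearly collinear anchors (< ``min_anchor_angle``°) are
    skipped and counted.
    """
    top = traj.topology
    mols = _ref_molecules(top, ref_type)
    if not mols:
        raise ValidationError(f"no molecules of type {ref_type!r}")
    for s in anchors:
        if any(s not in m for m in mols):
            raise ValidationError(f"anchor site {s!r} missing from a "
                                  f"{ref_type} molecule")
    t_idx = as_indices(target)
    n = int(np.ceil(2 * extent / voxel))
    counts = np.zeros((n, n, n))
    box = traj.frames[0].box
    n_instances = 0
    n_skipped = 0
    for frame in traj.frames:
        pos = frame.positions
        tpos = pos[t_idx]
        for sites in mols:
            p1 = pos[sites[anchors[0]]]
            v2 = minimum_image(pos[sites[anchors[1]]] - p1, box)
            v3 = minimum_image(pos[sites[anchors[2]]] - p1, box)
            ang = _angles_at(np.zeros(3), v2, v3, box)
            if ang < min_anchor_angle or ang > 180.0 - min_anchor_angle:
                n_skipped += 1
                continue
            ex = v2 / np.linalg.norm(v2)
            ez = v3 - np.dot(v3, ex) * ex
            ez = ez / np.linalg.norm(ez)
            ey = np.cross(ez, ex)
            d = minimum_image(tpos - p1, box)
            local = np.stack([d @ ex, d @ ey, d @ ez], axis=1)
            inside = np.all(np.abs(local) < extent, axis=1)
            ijk = np.floor((local[inside] + extent) / voxel).astype(int)
            ijk = np.clip(ijk, 0, n - 1)
            np.add.at(counts, (ijk[:, 0], ijk[:, 1], ijk[:, 2]), 1.0)
            n_instances += 1
    density = counts / (max(n_instances, 1) * voxel ** 3)
    return SDFGrid(voxel, extent, density, counts, tuple(anchors),
                   n_instances, n_skipped,
                   meta={"ref_type": ref_type, "n_targets": len(t_idx)})
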