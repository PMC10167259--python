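"""Config-driven orchestration of the full analysis suite.

A single YAML/dict config describes the input (a user-supplied trajectory
or a synthetic-mixture spec), the selections, and one parameter block per
analysis.  ``run_pipeline`` validates the config up front (unknown keys
are rejected), runs the stages in the order structure → hydrogen bonds →
energetics → dynamics, writes one CSV/JSON per analysis plus a manifest
(parameters, package version, seed, input digests), and is deterministic
for a fixed seed.  Stage failures abort with the stage name; logging goes
to stderr and never into the result files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path
from typing import Literal, Optional

import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from . import energetics, hbond, structure, synth
from . import dynamics as dyn
from .trajio import SiteGroup, SimulationBox, load_topology, load_trajectory

log = logging.getLogger("destraj.pipeline")

__all__ = ["AnalysisConfig", "ConfigError", "StageError", "run_pipeline",
           "load_config", "write_result_csv", "table2_check"]


class ConfigError(ValueError):
    """The configuration failed schema validation."""


class StageError(RuntimeError):
    """An analysis stage failed; ``stage`` names it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid")


class Selection(_Model):
    site_label: Optional[str] = None
    molecule_type: Optional[str] = None


class SynthSpec(_Model):
    kind: Literal["toy_des_mixture"] = "toy_des_mixture"
    n_salt: int = 30
    n_fa: int = 70
    fa_type: str = "CAP"
    planted_fraction: float = 0.5
    n_water: int = 0
    hydration_fraction: float = 1.0
    n_frames: int = 1
    frame_jitter: float = 0.0
    box: Optional[float] = None


class InputSpec(_Model):
    trajectory: str
    format: str = "XYZ"
    topology: str
    topology_format: str = "table"


class RDFSpec(_Model):
    sel_a: Selection
    sel_b: Selection
    dr: float = 0.05
    r_max: Optional[float] = None
    exclude_intramolecular: bool = True


class ADFSpec(_Model):
    sel_a: Selection
    sel_b: Selection
    sel_c: Selection
    cutoff_ab: float
    cutoff_bc: float
    bin_width: float = 1.0


class CDFDistAngleSpec(_Model):
    ref_type: str
    partner: Selection
    dist_site: str
    angle_sites: list[str] = Field(min_length=3, max_length=3)
    d_min: float = 0.0
    d_max: float = 6.0
    d_bins: int = 60
    a_bins: int = 36


class CDFDistDistSpec(_Model):
    ref_type: str
    partner_type: str
    pair_a: list[str] = Field(min_length=2, max_length=2)
    pair_b: list[str] = Field(min_length=2, max_length=2)
    r_max: float = 8.0
    bins: int = 40


class SDFSpec(_Model):
    ref_type: str
    anchors: list[str] = Field(min_length=3, max_length=3)
    target: Selection
    voxel: float = 0.5
    extent: float = 8.0


class HBondSpec(_Model):
    preset: Optional[str] = None
    donor: Optional[str] = None
    hydrogen: Optional[str] = None
    acceptor: Optional[str] = None
    dmax: Optional[float] = None
    amin: float = 0.0
    amax: float = 180.0

    def criterion(self) -> hbond.HBondCriterion:
        if self.preset is not None:
            try:
                return hbond.PRESETS[self.preset]
            except KeyError:
                raise ConfigError(f"unknown hbond preset {self.preset!r}")
        if None in (self.donor, self.hydrogen, self.acceptor, self.dmax):
            raise ConfigError("custom hbond criterion needs donor, hydrogen,"
                              " acceptor and dmax")
        return hbond.HBondCriterion(self.donor, self.hydrogen, self.acceptor,
                                    self.dmax, self.amin, self.amax)


class EnergiesSpec(_Model):
    # pair name -> [selection A, selection B]; selections by molecule type
    pairs: dict[str, list[Selection]]
    cutoff: Optional[float] = None


class StabilitySpec(_Model):
    hba_types: list[str] = ["CH", "CL"]
    hbd_types: list[str] = ["CAP", "LUA"]
    water_types: list[str] = ["WAT"]
    cutoff: Optional[float] = None


class MSDSpec(_Model):
    sel: Selection
    com: bool = False
    max_lag_fraction: float = 0.5
    beta_tol: float = 0.1


class VRDSpec(_Model):
    ref_type: str
    site_pair: list[str] = Field(min_length=2, max_length=2)
    max_lag_fraction: float = 0.5


class VACFSpec(_Model):
    sel: Selection
    com: bool = False
    max_lag_fraction: float = 0.5


class ViscositySpec(_Model):
    stress_csv: str
    volume: float
    temperature: float
    stress_unit: str = "atm"


class Analyses(_Model):
    rdf: Optional[RDFSpec] = None
    adf: Optional[ADFSpec] = None
    cdf_dist_angle: Optional[CDFDistAngleSpec] = None
    cdf_dist_dist: Optional[CDFDistDistSpec] = None
    sdf: Optional[SDFSpec] = None
    hbond: Optional[HBondSpec] = None
    occupancy: Optional[HBondSpec] = None
    energies: Optional[EnergiesSpec] = None
    stability: Optional[StabilitySpec] = None
    msd: Optional[MSDSpec] = None
    vacf: Optional[VACFSpec] = None
    vrd: Optional[VRDSpec] = None
    viscosity: Optional[ViscositySpec] = None


class AnalysisConfig(_Model):
    seed: int = 0
    out_dir: str = "destraj_out"
    log_level: str = "INFO"
    synth: Optional[SynthSpec] = None
    input: Optional[InputSpec] = None
    analyses: Analyses = Analyses()


def load_config(source) -> AnalysisConfig:
    """Validate a YAML path or a plain dict into an AnalysisConfig."""
    if isinstance(source, AnalysisConfig):
        return source
    if isinstance(source, (str, Path)):
        with open(source) as fh:
            source = yaml.safe_load(fh)
    try:
        cfg = AnalysisConfig.model_validate(source)
    except Exception as exc:
        raise ConfigError(str(exc))
    if (cfg.synth is None) == (cfg.input is None):
        raise ConfigError("exactly one of 'synth' or 'input' is required")
    return cfg


def write_result_csv(path, df: pd.DataFrame, params: dict) -> None:
    """CSV with a commented header carrying parameters and seed."""
    with open(path, "w") as fh:
        for key in sorted(params):
            fh.write(f"# {key}={params[key]}\n")
        df.to_csv(fh, index=False, float_format="%.12g", lineterminator="\n")


def _group(top, sel: Selection, name: str, com: bool = False) -> SiteGroup:
    idx = top.select(site_label=sel.site_label,
                     molecule_type=sel.molecule_type)
    return SiteGroup(name, idx, "by_molecule_com" if com else "by_atom")


def _type_group(top, types: list[str], name: str) -> SiteGroup:
    idx = np.concatenate([top.select(molecule_type=t) for t in types])
    return SiteGroup(name, np.sort(idx))


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def run_pipeline(config, out_dir: str | None = None) -> dict:
    """Run every configured analysis; returns {'manifest': ..., 'outputs':
    {analysis: path}, 'results': {analysis: object}} and writes everything
    under the configured output directory."""
    cfg = load_config(config)
    out = Path(out_dir or cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    logging.basicConfig(level=cfg.log_level)

    digests = {}
    if cfg.synth is not None:
        s = cfg.synth
        box = SimulationBox([s.box] * 3) if s.box else None
        traj = synth.gen_toy_des_mixture(
            n_salt=s.n_salt, n_fa=s.n_fa, fa_type=s.fa_type, box=box,
            planted_fraction=s.planted_fraction, n_water=s.n_water,
            hydration_fraction=s.hydration_fraction, seed=cfg.seed,
            n_frames=s.n_frames, frame_jitter=s.frame_jitter)
    else:
        topo = load_topology(cfg.input.topology,
                             format=cfg.input.topology_format)
        traj = load_trajectory(cfg.input.trajectory, format=cfg.input.format,
                               topology=topo)
        digests = {"trajectory": _sha256(cfg.input.trajectory),
                   "topology": _sha256(cfg.input.topology)}
    top = traj.topology

    outputs: dict = {}
    results: dict = {}

    def _stage(name, fn):
        t0 = time.perf_counter()
        try:
            fn()
        except Exception as exc:
            raise StageError(name, exc)
        log.info("stage %s finished in %.2f s", name, time.perf_counter() - t0)

    a = cfg.analyses
    base = {"seed": cfg.seed, "version": __version__}

    if a.rdf:
        def _run():
            ga = _group(top, a.rdf.sel_a, "A")
            gb = _group(top, a.rdf.sel_b, "B")
            res = structure.rdf(traj, ga, gb, dr=a.rdf.dr, r_max=a.rdf.r_max,
                                exclude_intramolecular=a.rdf.exclude_intramolecular)
            structure.first_minimum(res)
            path = out / "rdf.csv"
            write_result_csv(path, pd.DataFrame(
                {"r": res.r, "g": res.g, "cn": res.cn}),
                {**base, "dr": a.rdf.dr, "r_min1": res.r_min1,
                 "cn_at_first_min": res.cn_at_first_min, "rho": res.rho})
            outputs["rdf"] = str(path)
            results["rdf"] = res
        _stage("rdf", _run)

    if a.adf:
        def _run():
            res = structure.adf(traj, _group(top, a.adf.sel_a, "A"),
                                _group(top, a.adf.sel_b, "B"),
                                _group(top, a.adf.sel_c, "C"),
                                a.adf.cutoff_ab, a.adf.cutoff_bc,
                                a.adf.bin_width)
            path = out / "adf.csv"
            write_result_csv(path, pd.DataFrame(
                {"alpha": res.alpha, "density": res.density,
                 "counts": res.counts}),
                {**base, "cutoff_ab": a.adf.cutoff_ab,
                 "cutoff_bc": a.adf.cutoff_bc, "n_skipped": res.n_skipped})
            outputs["adf"] = str(path)
            results["adf"] = res
        _stage("adf", _run)

    if a.cdf_dist_angle:
        def _run():
            c = a.cdf_dist_angle
            res = structure.cdf_dist_angle(
                traj, c.ref_type, _group(top, c.partner, "partner"),
                c.dist_site, tuple(c.angle_sites),
                np.linspace(c.d_min, c.d_max, c.d_bins + 1),
                np.linspace(0.0, 180.0, c.a_bins + 1))
            path = out / "cdf_dist_angle.csv"
            d_c = 0.5 * (res.edges1[1:] + res.edges1[:-1])
            a_c = 0.5 * (res.edges2[1:] + res.edges2[:-1])
            dd, aa = np.meshgrid(d_c, a_c, indexing="ij")
            write_result_csv(path, pd.DataFrame(
                {"distance": dd.ravel(), "angle": aa.ravel(),
                 "value": res.values.ravel(), "count": res.counts.ravel()}),
                {**base, "ref_type": c.ref_type, "dist_site": c.dist_site})
            outputs["cdf_dist_angle"] = str(path)
            results["cdf_dist_angle"] = res
        _stage("cdf_dist_angle", _run)

    if a.cdf_dist_dist:
        def _run():
            c = a.cdf_dist_dist
            edges = np.linspace(0.0, c.r_max, c.bins + 1)
            res = structure.cdf_dist_dist(traj, c.ref_type, c.partner_type,
                                          tuple(c.pair_a), tuple(c.pair_b),
                                          edges, edges)
            path = out / "cdf_dist_dist.csv"
            c1 = 0.5 * (res.edges1[1:] + res.edges1[:-1])
            c2 = 0.5 * (res.edges2[1:] + res.edges2[:-1])
            dd, ee = np.meshgrid(c1, c2, indexing="ij")
            write_result_csv(path, pd.DataFrame(
                {"dist_a": dd.ravel(), "dist_b": ee.ravel(),
                 "value": res.values.ravel(), "count": res.counts.ravel()}),
                {**base, "ref_type": c.ref_type,
                 "partner_type": c.partner_type})
            outputs["cdf_dist_dist"] = str(path)
            results["cdf_dist_dist"] = res
        _stage("cdf_dist_dist", _run)

    if a.sdf:
        def _run():
            c = a.sdf
            res = structure.sdf(traj, c.ref_type, tuple(c.anchors),
                                _group(top, c.target, "target"),
                                voxel=c.voxel, extent=c.extent)
            path = out / "sdf.csv"
            centres = res.grid_centres
            nz = np.argwhere(res.counts > 0)
            write_result_csv(path, pd.DataFrame(
                {"x": centres[nz[:, 0]], "y": centres[nz[:, 1]],
                 "z": centres[nz[:, 2]],
                 "density": res.density[nz[:, 0], nz[:, 1], nz[:, 2]]}),
                {**base, "voxel": c.voxel, "extent": c.extent,
                 "anchors": ",".join(c.anchors),
                 "n_instances": res.n_instances})
            outputs["sdf"] = str(path)
            results["sdf"] = res
        _stage("sdf", _run)

    hseries = None
    if a.hbond:
        def _run():
            nonlocal hseries
            crit = a.hbond.criterion()
            hseries = hbond.hbond_count_series(traj, crit)
            path = out / "hbond_counts.csv"
            params = {**base, "dmax": crit.max_ha_distance,
                      "angle_window": f"{crit.angle_min}-{crit.angle_max}"}
            if len(hseries.counts) >= 30 and np.std(hseries.counts) > 0:
                fit = hbond.fit_gaussian_counts(hseries)
                params.update(fit_mean=fit.mean, fit_sigma=fit.sigma)
            write_result_csv(path, pd.DataFrame(
                {"frame": np.arange(hseries.n_frames),
                 "count": hseries.counts}), params)
            outputs["hbond"] = str(path)
            results["hbond"] = hseries
        _stage("hbond", _run)

    if a.occupancy:
        def _run():
            series = hseries if (hseries is not None and a.occupancy ==
                                 a.hbond) else \
                hbond.hbond_count_series(traj, a.occupancy.criterion())
            occ = hbond.occupancy(series)
            path = out / "occupancy.csv"
            write_result_csv(path, pd.DataFrame(
                {"donor_molecule": [p[0][0] for p in occ],
                 "acceptor_atom": [p[0][1] for p in occ],
                 "occupancy_pct": [p[1] for p in occ]}), base)
            outputs["occupancy"] = str(path)
            results["occupancy"] = occ
        _stage("occupancy", _run)

    if a.energies:
        def _run():
            pairs = {name: (_group(top, pa, f"{name}_a"),
                            _group(top, pb, f"{name}_b"))
                     for name, (pa, pb) in a.energies.pairs.items()}
            rep = energetics.interaction_energy_report(
                traj, pairs, cutoff=a.energies.cutoff)
            path = out / "energies.csv"
            write_result_csv(path, pd.DataFrame(
                {"pair": [p.name for p in rep],
                 "e_vdw": [p.e_vdw for p in rep],
                 "e_coul": [p.e_coul for p in rep],
                 "e_total": [p.e_total for p in rep]}),
                {**base, "cutoff": a.energies.cutoff})
            outputs["energies"] = str(path)
            results["energies"] = rep
        _stage("energies", _run)

    if a.stability:
        def _run():
            c = a.stability
            hba = _type_group(top, [t for t in c.hba_types
                                    if len(top.select(molecule_type=t))],
                              "hba")
            hbd = _type_group(top, [t for t in c.hbd_types
                                    if len(top.select(molecule_type=t))],
                              "hbd")
            wat = _type_group(top, c.water_types, "water")
            rep = energetics.interaction_energy_report(
                traj, {"hba_hbd": (hba, hbd), "hba_water": (hba, wat),
                       "hbd_water": (hbd, wat)}, cutoff=c.cutoff)
            e = {p.name: p.e_total for p in rep}
            s = energetics.stability_factor(e["hba_hbd"], e["hba_water"],
                                            e["hbd_water"])
            path = out / "stability.json"
            with open(path, "w") as fh:
                json.dump({**{p.name: p.e_total for p in rep}, "S": s,
                           "seed": cfg.seed}, fh, indent=2, sort_keys=True)
                fh.write("\n")
            outputs["stability"] = str(path)
            results["stability"] = s
        _stage("stability", _run)

    if a.msd:
        def _run():
            c = a.msd
            grp = _group(top, c.sel, "msd", com=c.com)
            res = dyn.msd(traj, grp, max_lag_fraction=c.max_lag_fraction)
            dyn.beta_exponent(res)
            fit = dyn.self_diffusion(res, beta_tol=c.beta_tol)
            path = out / "msd.csv"
            write_result_csv(path, pd.DataFrame(
                {"lag_ps": res.lags, "msd_A2": res.msd, "beta": res.beta}),
                {**base, "d_self_A2_ns": fit.d_self if fit else None,
                 "diffusive_window": fit.window if fit else None})
            outputs["msd"] = str(path)
            results["msd"] = (res, fit)
        _stage("msd", _run)

    if a.vacf:
        def _run():
            c = a.vacf
            grp = _group(top, c.sel, "vacf", com=c.com)
            res = dyn.vacf(traj, grp, max_lag_fraction=c.max_lag_fraction)
            path = out / "vacf.csv"
            write_result_csv(path, pd.DataFrame(
                {"lag_ps": res.lags, "cv": res.cv}),
                {**base, "t1_ps": res.t1, "t2_ps": res.t2})
            outputs["vacf"] = str(path)
            results["vacf"] = res
        _stage("vacf", _run)

    if a.vrd:
        def _run():
            c = a.vrd
            res = dyn.vrd(traj, c.ref_type, tuple(c.site_pair),
                          max_lag_fraction=c.max_lag_fraction)
            path = out / "vrd.csv"
            write_result_csv(path, pd.DataFrame(
                {"lag_ps": res.lags, "vrd": res.vrd}),
                {**base, "ref_type": c.ref_type,
                 "site_pair": "-".join(c.site_pair)})
            outputs["vrd"] = str(path)
            results["vrd"] = res
        _stage("vrd", _run)

    if a.viscosity:
        def _run():
            c = a.viscosity
            df = pd.read_csv(c.stress_csv, comment="#")
            t = df.iloc[:, 0].to_numpy(float)
            data = df.iloc[:, 1:4].to_numpy(float)
            res = dyn.gk_viscosity(data, c.volume, c.temperature,
                                   dt=float(t[1] - t[0]),
                                   stress_unit=c.stress_unit)
            digests["stress_csv"] = _sha256(c.stress_csv)
            path = out / "viscosity.csv"
            write_result_csv(path, pd.DataFrame(
                {"lag_ps": res.lags, "acf": res.acf, "eta_t_mPas": res.eta_t}),
                {**base, "eta_mPas": res.eta, "volume_A3": c.volume,
                 "temperature_K": c.temperature})
            outputs["viscosity"] = str(path)
            results["viscosity"] = res
        _stage("viscosity", _run)

    manifest = {
        "version": __version__,
        "seed": cfg.seed,
        "config": json.loads(cfg.model_dump_json()),
        "input_digests": digests,
        "outputs": outputs,
    }
    mpath = out / "manifest.json"
    with open(mpath, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"manifest": str(mpath), "outputs": outputs, "results": results}


def table2_check(energies_csv) -> pd.DataFrame:
    """Compute stability factors from a CSV of E_total values (columns
    des, ratio, pair, e_total with pairs salt_water/salt_fas/fas_water)."""
    df = pd.read_csv(energies_csv, comment="#")
    return energetics.stability_from_energies(df)
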