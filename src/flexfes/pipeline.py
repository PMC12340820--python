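"""End-to-end experiment orchestration with reproducible seeding.

An :class:`ExperimentConfig` fully specifies a desk-scale experiment — the
toy system, the sampling protocol, and the estimator settings. Every source
of randomness derives from the single master seed via fixed, named offsets,
so re-running an experiment from its persisted config reproduces the primary
outputs bitwise. Each stage appends a structured record to a
:class:`RunLog`.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import yaml

from . import io as fio
from .constants import DEFAULT_TEMPERATURE
from .essdyn import EssentialDynamics
from .metad import FESGrid, average_fes, reconstruct_fes, run_metadynamics
from .toysim import (
    LangevinParams,
    PotentialSpec,
    RestraintSpec,
    build_bead_complex,
    elastic_network_covariance,
    run_langevin,
    sample_gaussian_ensemble,
)
from .umbrella import (
    aggregate_conformers,
    bootstrap_pmf,
    make_staged_equilibration,
    make_window_schedule,
    statistical_inefficiency,
    subsample,
    wham_solve,
    WHAMResult,
)


class ConfigError(ValueError):
    """Invalid or inconsistent experiment configuration."""


def derive_seed(master: int, *path) -> int:
    """Deterministic per-stage seed below 2^31 from a master seed and a
    named offset path (e.g. ``derive_seed(1, "us", conformer, window)``)."""
    ents = [int(master) & 0x7FFFFFFF] + [
        zlib.crc32(str(p).encode()) for p in path
    ]
    return int(np.random.SeedSequence(ents).generate_state(1)[0] & 0x7FFFFFFF)


class RunLog:
    """Append-only structured log; one JSON record per stage event."""

    def __init__(self, path: Optional[Path] = None):
        self.path = Path(path) if path is not None else None
        self.records: list[dict] = []

    def log(self, stage: str, **fields) -> dict:
        rec = {"stage": stage, "wall_time": time.time(), **fields}
        self.records.append(rec)
        if self.path is not None:
            with open(self.path, "a") as fh:
                fh.write(json.dumps(rec) + "\n")
        return rec


@dataclass
class ExperimentConfig:
    """Declarative description of one experiment.

    ``kind`` selects the pipeline ("us", "ed" or "metad"); the matching
    section dict holds its settings. ``seed`` is the master seed; no stage
    ever seeds from the wall clock.
    """

    kind: str
    seed: int
    output_dir: str
    temperature: float = DEFAULT_TEMPERATURE
    potential: dict = field(default_factory=dict)
    us: dict = field(default_factory=dict)
    ed: dict = field(default_factory=dict)
    metad: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in ("us", "ed", "metad"):
            raise ConfigError(f"unknown experiment kind {self.kind!r}")
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an explicit integer")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    def make_potential(self) -> PotentialSpec:
        if not self.potential:
            raise ConfigError("config has no potential section")
        params = {k: v for k, v in self.potential.items() if k != "kind"}
        return PotentialSpec(self.potential["kind"], params)


def _prepare_outdir(config: ExperimentConfig):
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.to_yaml(outdir / "config.yaml")
    log = RunLog(outdir / "runlog.jsonl")
    return outdir, log


def _sample_window(potential, window, start_center, cfg, seed_base, temperature):
    """Staged equilibration then production sampling for one window."""
    stages = make_staged_equilibration(
        window,
        start_center,
        n_stages=cfg.get("equil_stages", 20),
        stage_length=cfg.get("equil_stage_ns", 2.5),
    )
    dt = cfg.get("timestep", 1e-5)
    friction = cfg.get("friction", 1.0)
    stage_steps = cfg.get("equil_stage_steps", 500)
    x = float(start_center)
    for i, (center, _) in enumerate(stages):
        s = run_langevin(
            potential,
            restraints=[RestraintSpec(center, window.force_constant)],
            params=LangevinParams(
                temperature=temperature,
                friction=friction,
                timestep=dt,
                n_steps=stage_steps,
                seed=derive_seed(seed_base, "equil", i),
            ),
            x0=x,
            save_every=stage_steps,
        )
        x = float(s.values[-1])
    prod = run_langevin(
        potential,
        restraints=[RestraintSpec(window.center, window.force_constant)],
        params=LangevinParams(
            temperature=temperature,
            friction=friction,
            timestep=dt,
            n_steps=cfg.get("production_steps", 40_000),
            seed=derive_seed(seed_base, "production"),
        ),
        x0=x,
        save_every=cfg.get("save_every", 10),
    )
    prod.window = window
    return prod


def run_us_experiment(config: ExperimentConfig) -> WHAMResult:
    """Windows -> staged equilibration -> production -> subsample ->
    aggregate across conformers -> WHAM (-> bootstrap), with artifacts."""
    if config.kind != "us":
        raise ConfigError("config kind must be 'us'")
    outdir, log = _prepare_outdir(config)
    cfg = config.us
    potential = config.make_potential()
    windows = make_window_schedule(
        cfg["interval"],
        cfg["n_windows"],
        cfg.get("force_constant", 1000.0),
        config.temperature,
    )
    log.log("windows", n_windows=len(windows), interval=list(cfg["interval"]),
            force_constant=cfg.get("force_constant", 1000.0))

    n_conf = cfg.get("n_conformers", 3)
    start = float(np.atleast_1d(potential.minimum_guess())[0])
    per_source = []
    for c in range(n_conf):
        series_list = []
        for w_idx, window in enumerate(windows):
            seed_base = derive_seed(config.seed, "us", c, w_idx)
            prod = _sample_window(
                potential, window, start, cfg, seed_base, config.temperature
            )
            prod.source = f"conformer-{c}"
            g = statistical_inefficiency(prod)
            sub = subsample(prod, g)
            series_list.append(sub)
            log.log(
                "window_sampled",
                conformer=c,
                window=w_idx,
                center=window.center,
                g=round(g, 3),
                n_raw=len(prod),
                n_subsampled=len(sub),
            )
        per_source.append(series_list)
    pooled = aggregate_conformers(per_source)
    log.log("aggregate", n_sources=n_conf,
            pooled_counts=[len(s) for s in pooled])

    paths = []
    for i, s in enumerate(pooled):
        p = outdir / f"window_{i:03d}.dat"
        fio.write_cv_series(s, p)
        paths.append(p.name)
    fio.write_window_metadata(windows, paths, outdir / "windows.meta")

    analysis_range = cfg.get("analysis_range", cfg["interval"])
    n_bins = cfg.get("n_bins", 40)
    tol = cfg.get("tolerance", 1e-6)
    max_iter = cfg.get("max_iterations", 100_000)
    n_trials = cfg.get("bootstrap_trials", 0)
    if n_trials:
        result = bootstrap_pmf(
            windows, pooled, analysis_range, n_bins=n_bins,
            n_trials=n_trials, seed=derive_seed(config.seed, "bootstrap"),
            tolerance=tol, max_iterations=max_iter,
            temperature=config.temperature,
        )
        log.log("bootstrap", n_trials=n_trials,
                discarded=result.n_bootstrap_discarded)
    else:
        result = wham_solve(
            windows, pooled, analysis_range, n_bins=n_bins, tolerance=tol,
            max_iterations=max_iter, temperature=config.temperature,
        )
    log.log("wham", n_iterations=result.n_iterations,
            converged=result.converged, n_dropped=result.n_dropped)
    fio.write_pmf(result, outdir / "pmf.tsv")
    return result


def run_ed_experiment(config: ExperimentConfig):
    """Frame generation -> selection -> superposition -> covariance ->
    modes -> variance fractions -> DCCM, with artifacts."""
    if config.kind != "ed":
        raise ConfigError("config kind must be 'ed'")
    outdir, log = _prepare_outdir(config)
    cfg = config.ed

    frame, domain_map = build_bead_complex(
        n_domains=cfg.get("n_domains", 5),
        beads_per_domain=cfg.get("beads_per_domain", 4),
        seed=derive_seed(config.seed, "complex"),
    )
    cov = elastic_network_covariance(
        frame,
        domain_map,
        intra_stiffness=cfg.get("intra_stiffness", 500.0),
        inter_stiffness=cfg.get("inter_stiffness", 50.0),
        temperature=config.temperature,
    )
    n_runs = cfg.get("n_runs", 3)
    per_run = cfg.get("per_run_frames", 200)
    last_n = cfg.get("last_n", per_run)
    if last_n > per_run:
        raise ConfigError("last_n cannot exceed per_run_frames")
    chunks = []
    for r in range(n_runs):
        traj = sample_gaussian_ensemble(
            frame, cov, per_run, seed=derive_seed(config.seed, "run", r)
        )
        chunks.append(traj.frames[per_run - last_n :])
    frames = np.concatenate(chunks, axis=0)
    log.log("frames", n_runs=n_runs, per_run=per_run, last_n=last_n,
            selected=int(frames.shape[0]))

    est = EssentialDynamics(superpose=cfg.get("superpose", True))
    est.fit(frames)
    n_modes = min(cfg.get("dccm_modes", 10), est.decomposition_.n_modes)
    dccm = est.cross_correlation(n_modes=n_modes)
    if dccm.degenerate_residues:
        log.log("dccm_degenerate", residues=list(dccm.degenerate_residues))
    log.log(
        "pca",
        n_frames=int(frames.shape[0]),
        var_frac_2=round(est.variance_fraction(min(2, est.decomposition_.n_modes)), 6),
        dccm_modes=n_modes,
    )

    labels = [f"B{i}" for i in range(frames.shape[1])]
    fio.write_labeled_matrix(dccm.matrix, labels, outdir / "dccm.tsv")
    np.savetxt(outdir / "eigenvalues.tsv", est.decomposition_.eigenvalues,
               fmt="%.10g", header="eigenvalue_nm2")
    fio.write_domain_map(domain_map, outdir / "domains.map")
    return est, dccm


def run_metad_experiment(config: ExperimentConfig) -> FESGrid:
    """Per-replica metadynamics -> per-replica FES -> replica average."""
    if config.kind != "metad":
        raise ConfigError("config kind must be 'metad'")
    outdir, log = _prepare_outdir(config)
    cfg = config.metad
    potential = config.make_potential()

    n_replicas = cfg.get("n_replicas", 15)
    seeds = cfg.get("replica_seeds")
    if seeds is None:
        seeds = [derive_seed(config.seed, "metad", r) for r in range(n_replicas)]
    if len(set(seeds)) != len(seeds):
        raise ConfigError("replica seeds must be distinct")
    if len(seeds) != n_replicas:
        raise ConfigError("need one seed per replica")

    grid_cfg = cfg.get("grid", {})
    lo = grid_cfg.get("lo", -1.0)
    hi = grid_cfg.get("hi", 1.0)
    n_nodes = grid_cfg.get("n", 101)
    if potential.ndim == 1:
        axes = (np.linspace(lo, hi, n_nodes),)
    else:
        lo2 = grid_cfg.get("lo2", lo)
        hi2 = grid_cfg.get("hi2", hi)
        n2 = grid_cfg.get("n2", n_nodes)
        axes = (np.linspace(lo, hi, n_nodes), np.linspace(lo2, hi2, n2))

    surfaces = []
    for r, seed in enumerate(seeds):
        params = LangevinParams(
            temperature=config.temperature,
            friction=cfg.get("friction", 1.0),
            timestep=cfg.get("timestep", 1e-4),
            n_steps=cfg.get("n_steps", 200_000),
            seed=seed,
        )
        series, bias = run_metadynamics(
            potential,
            params,
            stride=cfg.get("stride", 1000),
            height=cfg.get("height", 0.25),
            width=cfg.get("width", 0.08),
            save_every=cfg.get("save_every", 100),
        )
        fes = reconstruct_fes(bias, axes)
        surfaces.append(fes)
        fio.write_hills(bias, outdir / f"hills_{r:03d}.dat")
        log.log("replica", replica=r, seed=seed, n_hills=len(bias),
                empty=fes.empty_bias)
    averaged = average_fes(surfaces)
    if averaged.empty_bias:
        log.log("fes_degenerate", note="all replicas produced empty bias")
    fio.write_fes(averaged, outdir / "fes.tsv")
    log.log("average", n_replicas=len(surfaces))
    return averaged
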