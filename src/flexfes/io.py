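"""Plain-text readers and writers for the package's file dialects.

All files are whitespace-delimited text with ``#`` comments. Lengths are nm,
times ns, energies kcal/mol (free-energy tables) or kJ/mol (hill heights).
Index ranges in domain-map files are 0-based and half-open: ``KD 10-20``
selects beads 10..19.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import DomainMap, Trajectory
from .metad import FESGrid, MetaBias
from .umbrella import CVSeries, UmbrellaWindow, WHAMResult

_FMT = "%.10g"


def _f(x) -> str:
    return _FMT % float(x)


# --- trajectories (XYZ-like dialect) -----------------------------------


def write_xyz(traj: Trajectory, path) -> None:
    """Multi-frame XYZ-like text: bead count, ``time=<ns>``, then
    ``label x y z`` per bead."""
    with open(path, "w") as fh:
        for i in range(traj.n_frames):
            fh.write(f"{traj.n_beads}\n")
            fh.write(f"time={_f(traj.times[i])}\n")
            for lbl, xyz in zip(traj.bead_labels, traj.frames[i]):
                fh.write(f"{lbl} {_f(xyz[0])} {_f(xyz[1])} {_f(xyz[2])}\n")


def read_xyz(path) -> Trajectory:
    frames, times = [], []
    labels = None
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    pos = 0
    while pos < len(lines):
        if not lines[pos].strip():
            pos += 1
            continue
        n = int(lines[pos].split()[0])
        header = lines[pos + 1]
        t = float(header.split("time=")[1].split()[0]) if "time=" in header else len(times)
        block = lines[pos + 2 : pos + 2 + n]
        lbls, coords = [], []
        for ln in block:
            parts = ln.split()
            lbls.append(parts[0])
            coords.append([float(v) for v in parts[1:4]])
        frames.append(coords)
        times.append(t)
        labels = lbls
        pos += 2 + n
    return Trajectory(
        frames=np.asarray(frames, dtype=float),
        times=np.asarray(times, dtype=float),
        bead_labels=labels,
    )


def read_pdb_ca(path) -> Trajectory:
    """Extract Cα coordinates (nm) from a PDB file; models become frames."""
    from biotite.structure.io.pdb import PDBFile

    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    ca = stack[:, stack.atom_name == "CA"]
    labels = [f"{ch}{rid}" for ch, rid in zip(ca.chain_id, ca.res_id)]
    coords = np.asarray(ca.coord, dtype=float)
    return Trajectory(
        frames=coords / 10.0,  # A -> nm
        times=np.arange(coords.shape[0], dtype=float),
        bead_labels=labels,
    )


# --- domain maps --------------------------------------------------------


def write_domain_map(domain_map: DomainMap, path) -> None:
    """One line per domain: name, comma-separated half-open 0-based ranges."""
    with open(path, "w") as fh:
        for name in domain_map:
            idx = domain_map.indices(name)
            ranges = []
            start = prev = int(idx[0])
            for i in idx[1:]:
                i = int(i)
                if i != prev + 1:
                    ranges.append((start, prev + 1))
                    start = i
                prev = i
            ranges.append((start, prev + 1))
            body = ",".join(f"{a}-{b}" for a, b in ranges)
            fh.write(f"{name} {body}\n")


def read_domain_map(path) -> DomainMap:
    entries = {}
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#")[0].strip()
            if not ln:
                continue
            name, body = ln.split(None, 1)
            idx = []
            for tok in body.replace(",", " ").split():
                if "-" in tok:
                    a, b = tok.split("-")
                    idx.extend(range(int(a), int(b)))
                else:
                    idx.append(int(tok))
            entries[name] = idx
    return DomainMap(entries)


# --- CV time series and window metadata --------------------------------


def write_cv_series(series: CVSeries, path) -> None:
    """Two-column ``time value`` text (three columns for 2-CV series)."""
    vals = np.atleast_2d(series.values.T).T
    with open(path, "w") as fh:
        if series.source:
            fh.write(f"# source: {series.source}\n")
        for t, row in zip(series.times, vals):
            fh.write(" ".join([_f(t)] + [_f(v) for v in np.atleast_1d(row)]) + "\n")


def read_cv_series(path, window: Optional[UmbrellaWindow] = None) -> CVSeries:
    source = ""
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("# source:"):
            source = first.split(":", 1)[1].strip()
    arr = np.loadtxt(path, comments="#", ndmin=2)
    values = arr[:, 1] if arr.shape[1] == 2 else arr[:, 1:]
    return CVSeries(times=arr[:, 0], values=values, window=window, source=source)


def write_window_metadata(
    windows: Sequence[UmbrellaWindow], paths: Sequence[str], path
) -> None:
    """Per-window metadata: ``series_file center force_constant temperature``."""
    with open(path, "w") as fh:
        fh.write("# file center_nm k_kJ_mol_nm2 temperature_K\n")
        for w, p in zip(windows, paths):
            fh.write(f"{p} {_f(w.center)} {_f(w.force_constant)} {_f(w.temperature)}\n")


def read_window_metadata(path):
    """Returns (windows, series_paths)."""
    windows, paths = [], []
    with open(path) as fh:
        for ln in fh:
            ln = ln.split("#")[0].strip()
            if not ln:
                continue
            parts = ln.split()
            paths.append(parts[0])
            temp = float(parts[3]) if len(parts) > 3 else 310.0
            windows.append(UmbrellaWindow(float(parts[1]), float(parts[2]), temp))
    return windows, paths


def write_grossfield_input(
    windows: Sequence[UmbrellaWindow],
    data: Sequence[CVSeries],
    directory,
    kcal: bool = True,
) -> Path:
    """Write window time series plus a metadata file in the dialect of the
    Grossfield-lab ``wham`` program (``timeseries_file center spring``);
    spring constants are converted to kcal/(mol nm^2) when ``kcal``.

    Returns the metadata file path.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    meta = directory / "metadata.txt"
    scale = 1.0 / 4.184 if kcal else 1.0
    with open(meta, "w") as fh:
        for i, (w, s) in enumerate(zip(windows, data)):
            p = directory / f"window_{i:03d}.dat"
            write_cv_series(s, p)
            fh.write(f"{p} {_f(w.center)} {_f(w.force_constant * scale)}\n")
    return meta


# --- PMF / FES tables ---------------------------------------------------


def write_pmf(result: WHAMResult, path) -> None:
    """``bin_center free_energy ci_low ci_high n_samples`` table (kcal/mol)."""
    n = result.counts.sum(axis=0) if result.counts is not None else np.zeros_like(
        result.bin_centers
    )
    lo = result.ci_low if result.ci_low is not None else result.free_energy
    hi = result.ci_high if result.ci_high is not None else result.free_energy
    with open(path, "w") as fh:
        fh.write("# bin_center free_energy ci_low ci_high n_samples\n")
        for i, c in enumerate(result.bin_centers):
            fh.write(
                f"{_f(c)} {_f(result.free_energy[i])} {_f(lo[i])} "
                f"{_f(hi[i])} {int(n[i])}\n"
            )


def read_pmf(path) -> WHAMResult:
    arr = np.loadtxt(path, comments="#", ndmin=2)
    return WHAMResult(
        bin_centers=arr[:, 0],
        free_energy=arr[:, 1],
        ci_low=arr[:, 2],
        ci_high=arr[:, 3],
        converged=True,
    )


def write_hills(bias: MetaBias, path) -> None:
    """One hill per line: ``time center... width... height``."""
    with open(path, "w") as fh:
        fh.write(f"# n_cvs={bias.n_cvs}\n")
        for i in range(len(bias)):
            cols = (
                [bias.times[i]]
                + list(bias.centers[i])
                + list(bias.widths[i])
                + [bias.heights[i]]
            )
            fh.write(" ".join(_f(v) for v in cols) + "\n")


def read_hills(path) -> MetaBias:
    n_cvs = 1
    with open(path) as fh:
        first = fh.readline()
        if "n_cvs=" in first:
            n_cvs = int(first.split("n_cvs=")[1].split()[0])
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.size == 0:
        return MetaBias.empty(n_cvs)
    return MetaBias(
        centers=arr[:, 1 : 1 + n_cvs],
        widths=arr[:, 1 + n_cvs : 1 + 2 * n_cvs],
        heights=arr[:, 1 + 2 * n_cvs],
        times=arr[:, 0],
        n_cvs=n_cvs,
    )


def write_fes(grid: FESGrid, path) -> None:
    """Node-list text ``s1 [s2] F`` (kcal/mol)."""
    with open(path, "w") as fh:
        fh.write(f"# n_cvs={len(grid.axes)} replicas={grid.n_replicas_averaged}\n")
        if len(grid.axes) == 1:
            for x, v in zip(grid.axes[0], grid.values):
                fh.write(f"{_f(x)} {_f(v)}\n")
        else:
            for i, x in enumerate(grid.axes[0]):
                for j, y in enumerate(grid.axes[1]):
                    fh.write(f"{_f(x)} {_f(y)} {_f(grid.values[i, j])}\n")


def read_fes(path) -> FESGrid:
    arr = np.loadtxt(path, comments="#", ndmin=2)
    if arr.shape[1] == 2:
        return FESGrid(axes=(arr[:, 0],), values=arr[:, 1])
    ax1 = np.unique(arr[:, 0])
    ax2 = np.unique(arr[:, 1])
    vals = arr[:, 2].reshape(len(ax1), len(ax2))
    return FESGrid(axes=(ax1, ax2), values=vals)


# --- labeled square matrices (covariance, DCCM) -------------------------


def write_labeled_matrix(matrix: np.ndarray, labels: Sequence[str], path) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=list(labels), columns=list(labels))
    df.to_csv(path, sep="\t", float_format="%.10g")


def read_labeled_matrix(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    return df.to_numpy(), list(df.index)
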