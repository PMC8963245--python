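"""Plain-text file formats: multi-frame XYZ, energy sidecar TSV, profile
TSV, sample TSV and the 3-column legacy weights dialect.

All floats are written with fixed ``%.6f`` formatting so outputs are stable
and diff-able across platforms; readers compare parsed values, not bytes.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Trajectory
from .errors import (
    TrajectoryConsistencyError,
    TrajectoryFormatError,
)
from .reweighting import FreeEnergyProfile

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_sidecar",
    "read_sidecar",
    "write_trajectory",
    "read_trajectory",
    "write_legacy_weights",
    "write_profile",
    "read_profile",
    "write_samples_tsv",
    "read_samples_tsv",
    "write_manifest",
]

SIDECAR_COLUMNS = (
    "step", "time", "v_total", "v_peptide", "v_rest",
    "dv_peptide", "dv_rest", "dv_total",
)


# --------------------------------------------------------------------------
# XYZ
# --------------------------------------------------------------------------

def write_xyz(path, frames, elements, times=None) -> None:
    """Multi-frame standard XYZ; 2D coordinates are padded with z = 0.

    Bead classes are encoded as element symbols.  The comment line records
    the frame index, time and the native dimensionality so a round trip
    restores the original 2D/3D shape.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    ndim = frames.shape[2]
    with open(path, "w") as fh:
        for fi, frame in enumerate(frames):
            fh.write(f"{frame.shape[0]}\n")
            t = 0.0 if times is None else float(times[fi])
            fh.write(f"frame={fi} time={t:.6f} ndim={ndim}\n")
            for el, xyz in zip(elements, frame):
                x, y = xyz[0], xyz[1]
                z = xyz[2] if ndim == 3 else 0.0
                fh.write(f"{el} {x:.6f} {y:.6f} {z:.6f}\n")


def read_xyz(path):
    """Read a multi-frame XYZ file -> (frames (F, n, d), elements, times)."""
    frames, times, elements = [], [], None
    with open(path) as fh:
        lines = fh.readlines()
    i = 0
    ndim = 3
    while i < len(lines):
        if not lines[i].strip():
            i += 1
            continue
        try:
            n = int(lines[i].strip())
        except ValueError:
            raise TrajectoryFormatError(
                f"expected atom count, got {lines[i].strip()!r}", line=i + 1
            )
        if i + 1 + n >= len(lines) + 1 and n > 0:
            raise TrajectoryFormatError("truncated frame", line=i + 1)
        comment = lines[i + 1].strip()
        t = 0.0
        for tok in comment.split():
            if tok.startswith("time="):
                t = float(tok[5:])
            elif tok.startswith("ndim="):
                ndim = int(tok[5:])
        els, coords = [], []
        for j in range(n):
            k = i + 2 + j
            if k >= len(lines):
                raise TrajectoryFormatError("truncated frame", line=k)
            parts = lines[k].split()
            if len(parts) != 4:
                raise TrajectoryFormatError(
                    f"expected 'element x y z', got {lines[k].strip()!r}", line=k + 1
                )
            els.append(parts[0])
            coords.append([float(p) for p in parts[1:]])
        if elements is None:
            elements = els
        elif els != elements:
            raise TrajectoryFormatError("element list changed between frames", line=i + 1)
        frames.append(coords)
        times.append(t)
        i += 2 + n
    if not frames:
        raise TrajectoryFormatError("no frames found", line=1)
    arr = np.asarray(frames, dtype=float)
    if ndim == 2:
        arr = arr[:, :, :2]
    return arr, elements, np.asarray(times)


# --------------------------------------------------------------------------
# Energy sidecar
# --------------------------------------------------------------------------

def write_sidecar(path, traj: Trajectory) -> None:
    """Tab-separated per-frame energies and boosts, '#'-prefixed header.

    This sidecar is the weights file consumed by the reweighting stage.
    """
    with open(path, "w") as fh:
        fh.write("#" + "\t".join(SIDECAR_COLUMNS) + "\n")
        for i in range(len(traj)):
            vp, vr = traj.v_peptide[i], traj.v_rest[i]
            dvp, dvr = traj.dv_peptide[i], traj.dv_rest[i]
            fh.write(
                f"{i}\t{traj.times[i]:.6f}\t{vp + vr:.6f}\t{vp:.6f}\t{vr:.6f}"
                f"\t{dvp:.6f}\t{dvr:.6f}\t{dvp + dvr:.6f}\n"
            )


def read_sidecar(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise TrajectoryFormatError("sidecar must start with a '#' header", line=1)
        names = header[1:].split()
        df = pd.read_csv(fh, sep="\t", names=names)
    return df


def write_trajectory(prefix, traj: Trajectory, elements=None, system=None) -> tuple[str, str]:
    """Write ``<prefix>.xyz`` + ``<prefix>.tsv`` for one trajectory.

    If ``system`` is a toy peptide system the fixed receptor beads are
    appended to every frame and its element classes are used.
    """
    prefix = str(prefix)
    coords = traj.coords
    if system is not None:
        coords = np.asarray([system.full_coords(c) for c in coords])
        elements = system.elements
    if coords.ndim == 2:  # surface trajectory: one pseudo-particle
        coords = coords[:, None, :]
        if coords.shape[2] == 1:
            coords = np.concatenate([coords, np.zeros_like(coords)], axis=2)
    if elements is None:
        elements = ["X"] * coords.shape[1]
    xyz_path, tsv_path = prefix + ".xyz", prefix + ".tsv"
    write_xyz(xyz_path, coords, elements, times=traj.times)
    write_sidecar(tsv_path, traj)
    return xyz_path, tsv_path


def read_trajectory(prefix):
    """Inverse of :func:`write_trajectory` -> (frames, elements, sidecar df).

    Raises a consistency error when the XYZ frame count disagrees with the
    sidecar row count.
    """
    prefix = str(prefix)
    frames, elements, times = read_xyz(prefix + ".xyz")
    df = read_sidecar(prefix + ".tsv")
    if len(df) != len(frames):
        raise TrajectoryConsistencyError(
            f"sidecar has {len(df)} rows but XYZ has {len(frames)} frames"
        )
    return frames, elements, df


def write_legacy_weights(path, traj_or_df, beta: float) -> None:
    """3-column weights dialect ``dv  beta*dv  step`` for interoperability
    with PyReweighting-style tools."""
    if isinstance(traj_or_df, Trajectory):
        dv = traj_or_df.dv_total
        steps = np.arange(len(dv))
    else:
        dv = traj_or_df["dv_total"].to_numpy()
        steps = traj_or_df["step"].to_numpy()
    with open(path, "w") as fh:
        for d, s in zip(dv, steps):
            fh.write(f"{d:.6f}\t{beta * d:.6f}\t{int(s)}\n")


# --------------------------------------------------------------------------
# Profiles and samples
# --------------------------------------------------------------------------

def _fmt(x) -> str:
    return "NA" if not np.isfinite(x) else f"{x:.6f}"


def write_profile(path, profile: FreeEnergyProfile) -> None:
    """1D: ``bin_center F counts c1 c2``; 2D long format:
    ``x_center y_center F counts``.  Excluded bins are written as NA."""
    centers = profile.bin_centers
    with open(path, "w") as fh:
        if profile.ndim == 1:
            fh.write("#bin_center\tF\tcounts\tc1\tc2\n")
            for i, c in enumerate(centers[0]):
                fh.write(
                    f"{c:.6f}\t{_fmt(profile.f[i])}\t{int(profile.counts[i])}"
                    f"\t{_fmt(profile.c1[i])}\t{_fmt(profile.c2[i])}\n"
                )
        else:
            fh.write("#x_center\ty_center\tF\tcounts\n")
            for i, cx in enumerate(centers[0]):
                for j, cy in enumerate(centers[1]):
                    fh.write(
                        f"{cx:.6f}\t{cy:.6f}\t{_fmt(profile.f[i, j])}"
                        f"\t{int(profile.counts[i, j])}\n"
                    )


def read_profile(path) -> pd.DataFrame:
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise TrajectoryFormatError("profile must start with a '#' header", line=1)
        names = header[1:].split()
        df = pd.read_csv(fh, sep="\t", names=names, na_values=["NA"])
    return df


def write_samples_tsv(path, sample) -> None:
    """2-column ``coord deltaV`` (3-column with a 2D coordinate)."""
    coords = np.atleast_2d(np.asarray(sample.coordinate_values, dtype=float).T).T
    if coords.ndim == 1:
        coords = coords[:, None]
    with open(path, "w") as fh:
        if coords.shape[1] == 1:
            fh.write("#coord\tdeltaV\n")
            for c, d in zip(coords[:, 0], sample.boost_values):
                fh.write(f"{c:.6f}\t{d:.6f}\n")
        else:
            fh.write("#coord\tcoord2\tdeltaV\n")
            for (c1, c2), d in zip(coords, sample.boost_values):
                fh.write(f"{c1:.6f}\t{c2:.6f}\t{d:.6f}\n")


def read_samples_tsv(path):
    """Read a samples TSV -> (coords (N,) or (N,2), dv (N,))."""
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("#"):
            raise TrajectoryFormatError("samples file must start with '#' header", line=1)
        names = header[1:].split()
        df = pd.read_csv(fh, sep="\t", names=names)
    dv = df["deltaV"].to_numpy()
    if "coord2" in df.columns:
        return df[["coord", "coord2"]].to_numpy(), dv
    return df["coord"].to_numpy(), dv


def write_manifest(path, manifest: dict) -> None:
    """Machine-readable run manifest (seeds, stage summaries, file list)."""
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
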