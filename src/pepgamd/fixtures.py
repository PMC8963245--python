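"""Deterministic fixture bundle: small end-to-end runs for tests and docs.

Everything is generated at run time from a single master seed; the bundle
contains a boosted double-well run, a boosted three-state-landscape run, a
dual-boost toy-peptide run with three production replicas, and a synthetic
weighted-sample set, each with its energy sidecar.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np

from . import toy_systems as ts
from .engine import ProtocolSpec, run_gamd, run_pep_gamd
from .io import write_manifest, write_samples_tsv, write_trajectory

__all__ = ["make_fixtures"]


def _round(x, nd=6):
    return round(float(x), nd)


def _params_summary(p):
    return {
        "label": p.label,
        "n_samples": p.n_samples,
        "v_max": _round(p.v_max),
        "v_min": _round(p.v_min),
        "v_avg": _round(p.v_avg),
        "sigma_v": _round(p.sigma_v),
        "k0": None if p.k0 is None else _round(p.k0),
        "threshold_E": None if p.threshold_E is None else _round(p.threshold_E),
        "sigma_0": _round(p.sigma_0),
        "bound_mode": p.bound_mode,
    }


def make_fixtures(seed: int, outdir) -> dict:
    """Write the fixture bundle under ``outdir``; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": int(seed), "files": [], "runs": {}}

    # 1. double-well single-boost run
    dw = ts.make_double_well(5.0, 2.0)
    proto_dw = ProtocolSpec(
        n_cmd_steps=1000, n_equil_steps=3000, n_prod_steps=12000,
        n_replicas=1, dt=0.02, friction=1.0, temperature=1.0,
        seed=seed, sample_interval=5,
    )
    res_dw = run_gamd(dw, proto_dw, sigma_0=10.0)
    paths = write_trajectory(outdir / "double_well_prod1", res_dw.production[0])
    manifest["files"] += [str(p) for p in paths]
    manifest["runs"]["double_well"] = {
        "params": _params_summary(res_dw.params),
        "n_production_frames": len(res_dw.production[0]),
    }

    # 2. three-state landscape single-boost run
    land = ts.make_three_state_landscape(
        [(8.6, 10.0), (11.1, 10.0), (15.3, 10.0)], [5.0, 4.4, 4.6], [0.9, 0.9, 0.9]
    )
    proto_ls = ProtocolSpec(
        n_cmd_steps=1000, n_equil_steps=3000, n_prod_steps=15000,
        n_replicas=1, dt=0.02, friction=1.0, temperature=1.0,
        seed=seed + 11, sample_interval=5,
    )
    res_ls = run_gamd(land, proto_ls, sigma_0=10.0)
    paths = write_trajectory(outdir / "three_state_prod1", res_ls.production[0])
    manifest["files"] += [str(p) for p in paths]
    manifest["runs"]["three_state"] = {
        "params": _params_summary(res_ls.params),
        "n_production_frames": len(res_ls.production[0]),
    }

    # 3. toy peptide dual-boost run, three replicas
    system = ts.make_toy_peptide_system(4, seed)
    proto_pep = ProtocolSpec(
        n_cmd_steps=1000, n_equil_steps=3000, n_prod_steps=6000,
        n_replicas=3, dt=0.02, friction=1.0, temperature=1.0,
        seed=seed + 23, sample_interval=5,
    )
    res_pep = run_pep_gamd(system, proto_pep, sigma_0_L=10.0, sigma_0_D=10.0)
    for r, traj in enumerate(res_pep.production, start=1):
        paths = write_trajectory(outdir / f"peptide_prod{r}", traj, system=system)
        manifest["files"] += [str(p) for p in paths]
    manifest["runs"]["peptide"] = {
        "params_peptide": _params_summary(res_pep.params.peptide),
        "params_rest": _params_summary(res_pep.params.rest),
        "n_replicas": len(res_pep.production),
        "n_production_frames": [len(t) for t in res_pep.production],
    }

    # 4. synthetic weighted samples (Gaussian boost over a double-well PMF)
    target = lambda a: 2.0 * (a**2 - 1.0) ** 2  # noqa: E731
    sample = ts.synth_weighted_samples(
        target, ts.GaussianBoost(mean=6.0, sd=2.0), n=20000, seed=seed + 37,
        domain=(-2.0, 2.0),
    )
    write_samples_tsv(outdir / "synthetic_samples.tsv", sample)
    manifest["files"].append(str(outdir / "synthetic_samples.tsv"))
    manifest["runs"]["synthetic_samples"] = {"n": 20000, "boost": "gaussian(6, 2)"}

    blob = json.dumps(manifest["runs"], sort_keys=True).encode()
    manifest["content_hash"] = hashlib.sha256(blob).hexdigest()
    write_manifest(outdir / "manifest.json", manifest)
    manifest["files"].append(str(outdir / "manifest.json"))
    return manifest
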