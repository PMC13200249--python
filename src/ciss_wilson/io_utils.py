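"""Result serialization and run manifests.

All tabular output is comma-delimited UTF-8 with a header row and full
double precision, so identical configs reproduce byte-identical tables.
Each run writes a JSON manifest (tool version, config hash, seed, per-stage
status) before results land next to it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import ExperimentConfig

__all__ = ["RunManifest", "write_table", "write_manifest", "loop_reports_to_frame", "dynamics_to_frame", "trajectory_to_frame"]


@dataclass
class RunManifest:
    version: str
    config_hash: str
    seed: int
    started: str = ""
    finished: str = ""
    stages: dict = field(default_factory=dict)

    @classmethod
    def start(cls, cfg: ExperimentConfig) -> "RunManifest":
        return cls(
            version=__version__,
            config_hash=cfg.config_hash(),
            seed=cfg.seed,
            started=datetime.now(timezone.utc).isoformat(),
        )

    def finish(self, stage: str, status: str = "ok") -> None:
        self.stages[stage] = status
        self.finished = datetime.now(timezone.utc).isoformat()


def write_manifest(manifest: RunManifest, out_dir: str | Path) -> Path:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    path = out_dir / "manifest.json"
    with open(path, "w") as fh:
        json.dump(manifest.__dict__, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format="%.17g")
    return path


def loop_reports_to_frame(reports) -> pd.DataFrame:
    rows = []
    for r in reports:
        rows.append(
            {
                "path": "->".join(str(v) for v in r.path.vertices),
                "trace_re": float(np.real(r.trace)),
                "trace_im": float(np.imag(r.trace)),
                "phase": r.phase,
                "axis_x": float(r.axis[0]),
                "axis_y": float(r.axis[1]),
                "axis_z": float(r.axis[2]),
                "trivial": bool(r.trivial),
                "deviation": r.deviation,
            }
        )
    cols = ["path", "trace_re", "trace_im", "phase", "axis_x", "axis_y", "axis_z", "trivial", "deviation"]
    return pd.DataFrame(rows, columns=cols)


def dynamics_to_frame(result) -> pd.DataFrame:
    """Long-format (time, site, axis, expectation) table plus populations."""
    n_t, n_sites, _ = result.spins.shape
    rows = {
        "time_fs": np.repeat(result.times, n_sites),
        "site": np.tile(np.arange(1, n_sites + 1), n_t),
        "population": result.populations.ravel(),
        "sx": result.spins[:, :, 0].ravel(),
        "sy": result.spins[:, :, 1].ravel(),
        "sz": result.spins[:, :, 2].ravel(),
    }
    return pd.DataFrame(rows)


def trajectory_to_frame(traj, model) -> pd.DataFrame:
    from .open_system import acceptor_polarization

    n_t, n_sites = traj.populations.shape
    df = pd.DataFrame(
        {
            "time_fs": np.repeat(traj.times, n_sites),
            "site": np.tile(np.arange(1, n_sites + 1), n_t),
            "population": traj.populations.ravel(),
            "sx": traj.spins[:, :, 0].ravel(),
            "sy": traj.spins[:, :, 1].ravel(),
            "sz": traj.spins[:, :, 2].ravel(),
        }
    )
    pa = acceptor_polarization(traj, model)
    df["p_acceptor"] = np.repeat(pa, n_sites)
    return df
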