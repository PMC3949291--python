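"""Plain-text persistence of runs and analyses.

A run directory holds config.json, raster.csv (neuron_id,time_ms),
positions.csv, Matrix Market files for the initial/final weights, STDP
event counts and LBC adjacency, and mc_enabled.csv.  Everything needed to
regenerate the analyses without re-simulating.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.io import mmread, mmwrite

from .config import SimConfig
from .dynamics import SimResult, SpikeRaster
from .geometry import NetworkGeometry
from scipy.spatial.distance import pdist, squareform


def save_run(result: SimResult, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {
        "config": result.config.to_dict(),
        "seed": result.seed,
        "ablation": result.ablation,
        "mc_fraction": result.mc_fraction,
        "n_mc_events": result.n_mc_events,
        "duration_ms": result.raster.duration,
    }
    (out / "config.json").write_text(json.dumps(meta, indent=2))
    pd.DataFrame({"neuron_id": result.raster.neuron_ids,
                  "time_ms": result.raster.times}).to_csv(out / "raster.csv", index=False)
    pos = result.geometry.positions
    pd.DataFrame({"id": np.arange(pos.shape[0]), "x_um": pos[:, 0],
                  "y_um": pos[:, 1], "z_um": pos[:, 2]}).to_csv(
        out / "positions.csv", index=False)
    mmwrite(out / "weights_initial.mtx", sparse.coo_matrix(result.weights_initial))
    mmwrite(out / "weights_final.mtx", sparse.coo_matrix(result.weights_final))
    mmwrite(out / "stdp_counts.mtx", sparse.coo_matrix(result.stdp_counts))
    mmwrite(out / "lbc_adj.mtx", sparse.coo_matrix(result.lbc_adj.astype(np.int8)))
    pd.DataFrame({"mc_enabled": result.mc_enabled.astype(int)}).to_csv(
        out / "mc_enabled.csv", index=False)
    return out


def load_run(run_dir: str | Path) -> SimResult:
    """Rehydrate a saved run (MC neighbourhoods rebuilt from positions)."""
    run = Path(run_dir)
    meta = json.loads((run / "config.json").read_text())
    config = SimConfig.from_dict(meta["config"])
    raster_df = pd.read_csv(run / "raster.csv")
    pos = pd.read_csv(run / "positions.csv")[["x_um", "y_um", "z_um"]].to_numpy()
    distances = squareform(pdist(pos))
    geom = NetworkGeometry(positions=pos, distances=distances,
                           max_dist=float(distances.max()))
    ids = raster_df["neuron_id"].to_numpy(dtype=np.int32)
    ts = raster_df["time_ms"].to_numpy(dtype=float)
    order = np.lexsort((ids, ts))
    raster = SpikeRaster(ids[order], ts[order], geom.n_neurons,
                         float(meta["duration_ms"]))
    return SimResult(
        config=config, seed=meta["seed"], ablation=meta["ablation"],
        mc_fraction=meta["mc_fraction"], geometry=geom, raster=raster,
        weights_initial=np.asarray(mmread(run / "weights_initial.mtx").todense()),
        weights_final=np.asarray(mmread(run / "weights_final.mtx").todense()),
        stdp_counts=np.asarray(mmread(run / "stdp_counts.mtx").todense()).astype(np.int32),
        lbc_adj=np.asarray(mmread(run / "lbc_adj.mtx").todense()).astype(bool),
        mc_enabled=pd.read_csv(run / "mc_enabled.csv")["mc_enabled"].to_numpy(dtype=bool),
        n_mc_events=meta["n_mc_events"],
    )


class _JsonEncoder(json.JSONEncoder):
    def default(self, obj):
        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        return super().default(obj)


def write_json(data: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(data, indent=2, cls=_JsonEncoder))
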