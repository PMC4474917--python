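"""Artifact output: spike tables, weight snapshots, metric reports."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

__all__ = ["write_spikes", "write_snapshots", "write_metrics",
           "write_protocol_table"]


def write_spikes(path, sim_result, seed: int, cfg_hash: str) -> None:
    """Two-column delimited text (time_ms, neuron_id) with a header."""
    path = Path(path)
    header = (f"seed={seed} config={cfg_hash}\n"
              "time_ms\tneuron_id")
    np.savetxt(path, sim_result.spikes(), fmt=["%.3f", "%d"],
               delimiter="\t", header=header)


def write_snapshots(path, snapshots, cfg_hash: str) -> None:
    """Weight matrices in an HDF5 container: W_init, W_batch_{k}."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["config"] = cfg_hash
        f.create_dataset("W_init", data=snapshots[0])
        for k, W in enumerate(snapshots[1:], start=1):
            f.create_dataset(f"W_batch_{k}", data=W)


def write_metrics(path, metrics: dict, seed: int, cfg_hash: str) -> None:
    """Flat key-value JSON report for machine diffing."""
    payload = {"seed": seed, "config": cfg_hash}
    for k, v in metrics.items():
        if isinstance(v, dict):
            payload.update({f"{k}.{kk}": vv for kk, vv in v.items()})
        else:
            payload[k] = v
    Path(path).write_text(json.dumps(payload, indent=1, default=float))


def write_protocol_table(path, protocol, cfg_hash: str) -> None:
    """Audit schedule: segment_index, orientation_or_NA, duration_ms."""
    lines = [f"# config={cfg_hash}", "segment_index\torientation\tduration_ms"]
    for i, s in enumerate(protocol.segments):
        o = "NA" if s.orientation is None else f"{s.orientation:g}"
        lines.append(f"{i}\t{o}\t{s.duration_ms:g}")
    Path(path).write_text("\n".join(lines) + "\n")
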