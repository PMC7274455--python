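"""Containers for binary functional networks and panels of them over time.

A :class:`FunctionalNetwork` is one undirected, unweighted graph on the
electrodes of a single device at a single recording day (DIV).  A
:class:`NetworkPanel` stacks such graphs for several devices over a shared
DIV grid and a common node set; it is the data object the block-model
samplers consume.  Panels round-trip through plain-text artifacts: one 0/1
adjacency table per (device, DIV) plus a JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["FunctionalNetwork", "NetworkPanel", "write_panel", "read_panel"]


def _check_adjacency(a: np.ndarray) -> np.ndarray:
    a = np.asarray(a)
    if a.ndim != 2 or a.shape[0] != a.shape[1]:
        raise ValueError(f"adjacency must be square, got shape {a.shape}")
    vals = np.unique(a)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("adjacency entries must be 0/1")
    if not np.array_equal(a, a.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(a) != 0):
        raise ValueError("adjacency must have a zero diagonal (no self-loops)")
    return a.astype(np.uint8)


@dataclass(frozen=True)
class FunctionalNetwork:
    """Binary symmetric hollow adjacency for one device at one DIV."""

    adjacency: np.ndarray
    channels: tuple
    device_id: str = ""
    div: int = 0

    def __post_init__(self):
        a = _check_adjacency(self.adjacency)
        object.__setattr__(self, "adjacency", a)
        object.__setattr__(self, "channels", tuple(self.channels))
        if len(self.channels) != a.shape[0]:
            raise ValueError("channel list length must match adjacency size")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("duplicate channel ids")

    @property
    def n(self) -> int:
        return self.adjacency.shape[0]

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def density(self) -> float:
        n = self.n
        if n < 2:
            return 0.0
        return float(self.adjacency.sum() / (n * (n - 1)))


@dataclass
class NetworkPanel:
    """Networks for several devices over a common DIV grid and node set.

    ``adjacency`` has shape (n_devices, n_divs, n, n); ``observed`` marks
    which (device, DIV) cells actually hold a recording — unobserved cells
    are simply omitted from any likelihood.
    """

    devices: list
    divs: list
    channels: list
    adjacency: np.ndarray
    observed: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.devices = list(self.devices)
        self.divs = [int(t) for t in self.divs]
        self.channels = list(self.channels)
        a = np.asarray(self.adjacency, dtype=np.uint8)
        d, T, n = len(self.devices), len(self.divs), len(self.channels)
        if a.shape != (d, T, n, n):
            raise ValueError(
                f"adjacency shape {a.shape} does not match "
                f"(devices={d}, divs={T}, n={n})"
            )
        if any(b <= c for b, c in zip(self.divs[1:], self.divs[:-1])):
            raise ValueError("divs must be strictly increasing")
        if self.observed is None:
            self.observed = np.ones((d, T), dtype=bool)
        self.observed = np.asarray(self.observed, dtype=bool)
        if self.observed.shape != (d, T):
            raise ValueError("observed mask shape must be (devices, divs)")
        for di in range(d):
            for ti in range(T):
                if self.observed[di, ti]:
                    _check_adjacency(a[di, ti])
        self.adjacency = a

    @property
    def n(self) -> int:
        return len(self.channels)

    @property
    def n_devices(self) -> int:
        return len(self.devices)

    @property
    def n_divs(self) -> int:
        return len(self.divs)

    def network(self, device, div) -> FunctionalNetwork:
        di = self.devices.index(device)
        ti = self.divs.index(int(div))
        if not self.observed[di, ti]:
            raise KeyError(f"no recording for device {device!r} at DIV {div}")
        return FunctionalNetwork(
            self.adjacency[di, ti], tuple(self.channels), str(device), int(div)
        )

    def subset_devices(self, devices) -> "NetworkPanel":
        idx = [self.devices.index(dv) for dv in devices]
        return NetworkPanel(
            [self.devices[i] for i in idx],
            self.divs,
            self.channels,
            self.adjacency[idx],
            self.observed[idx],
        )

    def drop_div(self, div) -> "NetworkPanel":
        """Panel without one DIV column (e.g. to hold out the last day)."""
        ti = self.divs.index(int(div))
        keep = [i for i in range(self.n_divs) if i != ti]
        return NetworkPanel(
            self.devices,
            [self.divs[i] for i in keep],
            self.channels,
            self.adjacency[:, keep],
            self.observed[:, keep],
        )

    @classmethod
    def from_networks(cls, networks) -> "NetworkPanel":
        """Assemble a panel from FunctionalNetworks sharing one channel order."""
        networks = list(networks)
        if not networks:
            raise ValueError("no networks given")
        channels = networks[0].channels
        for g in networks:
            if g.channels != channels:
                raise ValueError("all networks must share the same channel ordering")
        devices = sorted({g.device_id for g in networks})
        divs = sorted({g.div for g in networks})
        n = len(channels)
        adj = np.zeros((len(devices), len(divs), n, n), dtype=np.uint8)
        obs = np.zeros((len(devices), len(divs)), dtype=bool)
        for g in networks:
            di, ti = devices.index(g.device_id), divs.index(g.div)
            if obs[di, ti]:
                raise ValueError(f"duplicate network for ({g.device_id}, {g.div})")
            adj[di, ti] = g.adjacency
            obs[di, ti] = True
        return cls(devices, divs, list(channels), adj, obs)


def write_panel(panel: NetworkPanel, out_dir) -> Path:
    """Write one adjacency TSV per observed (device, DIV) plus a manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries = []
    for di, dev in enumerate(panel.devices):
        for ti, div in enumerate(panel.divs):
            if not panel.observed[di, ti]:
                continue
            fname = f"adjacency_{dev}_div{div}.tsv"
            df = pd.DataFrame(
                panel.adjacency[di, ti],
                columns=[str(c) for c in panel.channels],
            )
            df.to_csv(out / fname, sep="\t", index=False)
            entries.append({"device": str(dev), "div": int(div), "path": fname})
    manifest = {
        "devices": [str(d) for d in panel.devices],
        "divs": [int(t) for t in panel.divs],
        "channels": [str(c) for c in panel.channels],
        "networks": entries,
    }
    mpath = out / "panel.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_panel(manifest_path) -> NetworkPanel:
    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    devices = manifest["devices"]
    divs = [int(t) for t in manifest["divs"]]
    channels = manifest["channels"]
    n = len(channels)
    adj = np.zeros((len(devices), len(divs), n, n), dtype=np.uint8)
    obs = np.zeros((len(devices), len(divs)), dtype=bool)
    for entry in manifest["networks"]:
        di = devices.index(entry["device"])
        ti = divs.index(int(entry["div"]))
        df = pd.read_csv(mpath.parent / entry["path"], sep="\t")
        if list(df.columns) != [str(c) for c in channels]:
            raise ValueError(f"channel header mismatch in {entry['path']}")
        adj[di, ti] = df.to_numpy()
        obs[di, ti] = True
    return NetworkPanel(devices, divs, channels, adj, obs)
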