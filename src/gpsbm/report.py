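"""Study-level reporting: one joint model per dataset, condition-wise
community tables, trend labels for the eta(t) curves, and spike-train
diagnostics.

A *study* bundles several MEA devices under a handful of experimental
conditions recorded over a shared DIV grid. One block model is fit jointly
over every device and DIV of the study; conditions are distinguished only
at reporting time, so the community columns of all per-condition tables
refer to the same (size-ordered) communities and can be compared directly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .panel import NetworkPanel, read_panel
from .ephys import SpikeRecording, read_spikes, build_network, mean_firing_rate
from .mcmc import MCMCConfig, PriorSpec, fit_tsbm
from .summarize import FitSummary, relabel_by_size

__all__ = [
    "StudyConfig",
    "ConditionReport",
    "TrendRules",
    "run_study",
    "inactive_community",
    "classify_community_trend",
    "firing_rate_vs_degree",
]

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Declarative description of one study run.

    ``conditions`` maps condition labels to device-id lists. Input is
    either a directory of spike tables (``spikes_dir``; one
    ``<device>_div<div>.tsv`` + sidecar per recording) or a pre-built panel
    manifest (``panel_manifest``). Missing (device, DIV) cells are allowed.
    """

    conditions: dict
    divs: list
    spikes_dir: str | None = None
    panel_manifest: str | None = None
    threshold: float = 0.20
    bin_width: float = 0.010
    burst_min_spikes: int = 4
    burst_window: float = 0.100
    global_min_channels: int = 4
    global_window: float = 0.250
    k: int = 10
    mcmc: MCMCConfig = field(default_factory=MCMCConfig)
    priors: PriorSpec = field(default_factory=PriorSpec)
    seed: int = 0
    min_community_size: int = 1
    out_dir: str = "study_out"

    @classmethod
    def from_json(cls, path) -> "StudyConfig":
        raw = json.loads(Path(path).read_text())
        if "mcmc" in raw:
            raw["mcmc"] = MCMCConfig(**raw["mcmc"])
        if "priors" in raw:
            raw["priors"] = PriorSpec(**raw["priors"])
        return cls(**raw)


@dataclass
class ConditionReport:
    """Per-condition slice of the joint fit."""

    condition: str
    devices: list
    occupied_per_device: dict        # device -> # communities with >= min nodes
    density_table: pd.DataFrame      # devices x communities node counts
    eta_mean: np.ndarray             # (k, k, T), shared across conditions
    eta_ci: np.ndarray
    divs: np.ndarray
    trend_labels: dict               # community pair "i-j" -> label


@dataclass(frozen=True)
class TrendRules:
    """Quantified thresholds for the qualitative trend vocabulary."""

    inactive: float = 0.05
    transient_hi: float = 0.5
    transient_lo: float = 0.2
    increase: float = 0.3
    persistent: float = 0.5
    monotone_rmse: float = 0.05


def classify_community_trend(eta_curve, rules: TrendRules = TrendRules()) -> str:
    """Rule-based label for one eta(t) curve.

    inactive: all points < 0.05; persistent: all points > 0.5; transient:
    exactly one point > 0.5 and the rest < 0.2; increasing: last point
    exceeds the first by > 0.3 and an isotonic (monotone non-decreasing)
    fit reproduces the curve to within ``monotone_rmse``; otherwise mixed.
    """
    curve = np.asarray(eta_curve, dtype=float)
    if curve.ndim != 1 or len(curve) < 3:
        raise ValueError("trend classification needs a curve on >= 3 DIVs")
    if np.all(curve < rules.inactive):
        return "inactive"
    if np.all(curve > rules.persistent):
        return "persistent"
    high = curve > rules.transient_hi
    if high.sum() == 1 and np.all(curve[~high] < rules.transient_lo):
        return "transient"
    if curve[-1] > curve[0] + rules.increase:
        from sklearn.isotonic import IsotonicRegression

        fit = IsotonicRegression(increasing=True).fit_transform(
            np.arange(len(curve)), curve
        )
        if float(np.sqrt(np.mean((fit - curve) ** 2))) <= rules.monotone_rmse:
            return "increasing"
    return "mixed"


def inactive_community(
    summary: FitSummary, cutoff: float = 0.05
) -> int | None:
    """The community (1-based, most populated first) whose posterior-mean
    connection probability with every community — itself included — stays
    below ``cutoff`` at all DIVs, or None. Such a community collects the
    electrodes that never interact with the rest of the device."""
    for c in range(summary.k):
        if summary.community_counts.sum(axis=0)[c] == 0:
            continue
        if np.all(summary.eta_mean[c, :, :] < cutoff):
            return c + 1
    return None


def _build_panel_from_spikes(cfg: StudyConfig):
    recs = []
    spikes_dir = Path(cfg.spikes_dir)
    devices = [dv for devs in cfg.conditions.values() for dv in devs]
    for dev in devices:
        for div in cfg.divs:
            path = spikes_dir / f"{dev}_div{div}.tsv"
            if not path.exists():
                continue
            recs.append(read_spikes(path))
    missing_devices = {
        dv for dv in devices
        if not any(r.device_id == dv for r in recs)
    }
    if missing_devices:
        raise FileNotFoundError(
            f"no spike recordings found for device(s) {sorted(missing_devices)} "
            f"in {spikes_dir}"
        )
    networks = [
        build_network(
            r, cfg.threshold, cfg.bin_width, cfg.burst_min_spikes,
            cfg.burst_window, cfg.global_min_channels, cfg.global_window,
        )
        for r in recs
    ]
    return NetworkPanel.from_networks(networks), recs


def run_study(config: StudyConfig):
    """Build (or load) the panel, fit one joint model over every device and
    DIV, relabel, and emit one :class:`ConditionReport` per condition plus a
    machine-readable bundle (CSV tables + diagnostics JSON) in
    ``config.out_dir``. Fully seeded and deterministic.
    """
    if config.panel_manifest is not None:
        panel = read_panel(config.panel_manifest)
    elif config.spikes_dir is not None:
        panel, _ = _build_panel_from_spikes(config)
    else:
        raise ValueError("config must give spikes_dir or panel_manifest")
    wanted = [dv for devs in config.conditions.values() for dv in devs]
    unknown = [dv for dv in wanted if dv not in panel.devices]
    if unknown:
        raise ValueError(f"config references unknown device(s) {unknown}")
    panel = panel.subset_devices(wanted)

    mcmc = MCMCConfig(
        n_chains=config.mcmc.n_chains, n_samples=config.mcmc.n_samples,
        n_warmup=config.mcmc.n_warmup, seed=config.seed, thin=config.mcmc.thin,
    )
    trace = fit_tsbm(panel, config.k, mcmc, config.priors)
    summary = relabel_by_size(trace)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    reports = {}
    count_rows, trend_rows, eta_rows = [], [], []
    trends = {}
    for i in range(summary.k):
        for j in range(i + 1):
            label = classify_community_trend(summary.eta_mean[i, j])
            trends[f"{j + 1}-{i + 1}"] = label
            trend_rows.append(
                {"pair": f"{j + 1}-{i + 1}", "label": label}
            )
            for ti, div in enumerate(summary.divs):
                eta_rows.append(
                    {
                        "community_i": j + 1, "community_j": i + 1,
                        "div": int(div),
                        "eta_mean": summary.eta_mean[i, j, ti],
                        "eta_lo": summary.eta_ci[0, i, j, ti],
                        "eta_hi": summary.eta_ci[1, i, j, ti],
                    }
                )
    for cond, devs in config.conditions.items():
        didx = [summary.devices.index(dv) for dv in devs]
        counts = summary.community_counts[didx]
        occupied = {
            dv: int((counts[a] >= config.min_community_size).sum())
            for a, dv in enumerate(devs)
        }
        density = pd.DataFrame(
            counts, index=devs,
            columns=[f"community_{c + 1}" for c in range(summary.k)],
        )
        reports[cond] = ConditionReport(
            condition=cond, devices=list(devs),
            occupied_per_device=occupied,
            density_table=density,
            eta_mean=summary.eta_mean, eta_ci=summary.eta_ci,
            divs=summary.divs, trend_labels=trends,
        )
        for dv in devs:
            count_rows.append(
                {"condition": cond, "device": dv, "n_communities": occupied[dv]}
            )
        density.to_csv(out / f"density_table_{cond}.csv")
    pd.DataFrame(count_rows).to_csv(out / "community_counts.csv", index=False)
    pd.DataFrame(eta_rows).to_csv(out / "eta_curves.csv", index=False)
    pd.DataFrame(trend_rows).to_csv(out / "trend_labels.csv", index=False)
    diag = {k: v for k, v in summary.diagnostics.items()}
    diag["occupied_k"] = summary.occupied_k
    diag["seed"] = config.seed
    (out / "diagnostics.json").write_text(json.dumps(diag, indent=1))
    return reports


def firing_rate_vs_degree(recordings, panel: NetworkPanel):
    """Per-(device, DIV, channel) mean firing rate vs node degree, with a
    Spearman rank correlation and Fisher-z 95% CI.

    A flat correlation (CI covering 0) indicates that graph connectivity is
    not explained by electrode activity levels alone. When either variable
    is constant the correlation is undefined and reported as None.
    Returns (DataFrame, rho, (ci_lo, ci_hi)).
    """
    rows = []
    for rec in recordings:
        if list(rec.channels) != [str(c) for c in panel.channels] and list(
            rec.channels
        ) != list(panel.channels):
            raise ValueError(
                f"recording {rec.device_id} DIV {rec.div} channels do not "
                "match the panel"
            )
        g = panel.network(rec.device_id, rec.div)
        rates = mean_firing_rate(rec)
        degrees = g.degrees()
        for ch, r, deg in zip(rec.channels, rates, degrees):
            rows.append(
                {
                    "device": rec.device_id, "div": rec.div, "channel": ch,
                    "firing_rate_hz": float(r), "degree": int(deg),
                }
            )
    df = pd.DataFrame(rows)
    if df["degree"].nunique() < 2 or df["firing_rate_hz"].nunique() < 2:
        return df, None, (None, None)
    rho = float(stats.spearmanr(df["firing_rate_hz"], df["degree"]).statistic)
    n = len(df)
    if n > 3 and abs(rho) < 1:
        zr = np.arctanh(rho)
        half = 1.959964 / np.sqrt(n - 3)
        ci = (float(np.tanh(zr - half)), float(np.tanh(zr + half)))
    else:
        ci = (None, None)
    return df, rho, ci
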