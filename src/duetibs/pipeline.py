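"""End-to-end orchestration: simulate -> behavior -> IBS -> stats -> controls
-> brain-behavior, from one YAML config, with per-stage seeds and a manifest.

Every random stage derives its seed from the global seed plus the stage name,
so a re-run with the same config is bit-identical; the manifest records
seeds, the config, and SHA-256 hashes of all written artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior as bhv
from . import controls as ctl
from .design import cell_index, make_design
from .envelope import WindowGrid, band_envelope, envelope_phase
from .io import write_keystrokes
from .mixed import fit_linear_mixed, fit_logistic_mixed
from .simulate import (
    PhaseSession, SimParams, simulate_dual_eeg, simulate_envelope_phase_session,
    simulate_keystroke_session,
)
from .stats import PermutationConfig, cluster_report, permutation_test

logger = logging.getLogger("duetibs")

STAGES = ("simulate", "behavior", "ibs", "cluster", "controls", "brainbehavior")

_SCHEMA = {
    "seed": int,
    "stages": list,
    "sim": dict,
    "grid": dict,
    "perm": dict,
    "bands": list,
    "rois": list,
    "controls": dict,
    "brain_behavior": dict,
}

_SIM_KEYS = {
    "mode", "n_pairs", "trials_per_cell", "sfreq", "kappa", "coupling_mode",
    "phase_drift", "modulation_depth", "noise_exponent", "motor_noise_sigma",
    "anticipation_bias", "adaptation_gain", "noise_scale", "bands",
}


def load_config(path_or_dict) -> dict:
    """Load and schema-validate a run configuration (unknown keys rejected)."""
    if isinstance(path_or_dict, (str, Path)):
        with open(path_or_dict) as f:
            cfg = yaml.safe_load(f)
    else:
        cfg = dict(path_or_dict)
    unknown = set(cfg) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, typ in _SCHEMA.items():
        if key in cfg and not isinstance(cfg[key], typ):
            raise ValueError(f"config key {key!r} must be {typ.__name__}")
    sim_unknown = set(cfg.get("sim", {})) - _SIM_KEYS
    if sim_unknown:
        raise ValueError(f"unknown sim config keys: {sorted(sim_unknown)}")
    bad_stages = set(cfg.get("stages", [])) - set(STAGES)
    if bad_stages:
        raise ValueError(f"unknown stages: {sorted(bad_stages)}")
    cfg.setdefault("seed", 0)
    cfg.setdefault("stages", list(STAGES))
    cfg.setdefault("sim", {})
    cfg.setdefault("bands", ["gamma"])
    cfg.setdefault("rois", ["GLOBAL"])
    return cfg


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed derived from the global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2 ** 31)


def default_config() -> dict:
    """Small end-to-end demo configuration on synthetic data."""
    return load_config({
        "seed": 0,
        "sim": {
            "mode": "phase", "n_pairs": 6, "trials_per_cell": 12,
            "sfreq": 50.0,
            "kappa": {"pause": {"congruent": 4.0, "incongruent": 0.3}},
        },
        "grid": {"width": 2.0, "step": 0.1, "start": 1.0, "end": 14.2},
        "perm": {"n_perm": 200},
        "controls": {"baseline_reps": 5},
        "brain_behavior": {
            "window": [6.7, 9.3],
            "linear_outcomes": ["entry_asynchrony_s"],
            "logistic_outcomes": ["iki_difference_s"],
        },
    })


def _hash_file(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


class Run:
    """One pipeline run rooted at ``out_dir``; stages cache their artifacts."""

    def __init__(self, config: dict, out_dir):
        self.config = load_config(config)
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.grid = WindowGrid(**self.config.get("grid", {}))
        self.perm = PermutationConfig(
            seed=stage_seed(self.config["seed"], "cluster"),
            **self.config.get("perm", {}))
        self.sessions: dict[str, list[PhaseSession]] = {}
        self.timings: dict[str, float] = {}

    # -- stages --------------------------------------------------------
    def run(self, stages=None) -> dict:
        stages = list(stages or self.config["stages"])
        for stage in stages:
            t0 = time.time()
            getattr(self, f"stage_{stage}")()
            self.timings[stage] = round(time.time() - t0, 3)
            logger.info("stage %s done in %.2fs", stage, self.timings[stage])
        return self.write_manifest(stages)

    def stage_simulate(self):
        cfg = self.config["sim"]
        seed = stage_seed(self.config["seed"], "simulate")
        n_pairs = int(cfg.get("n_pairs", 6))
        tpc = int(cfg.get("trials_per_cell", 12))
        design = make_design(n_pairs, tpc, seed)
        design.to_csv(self.out_dir / "design.csv", index=False)

        params = SimParams(
            n_pairs=n_pairs, trials_per_cell=tpc, rng_seed=seed,
            motor_noise_sigma=float(cfg.get("motor_noise_sigma", 10.0)),
            anticipation_bias=float(cfg.get("anticipation_bias", 2.0)),
            adaptation_gain=float(cfg.get("adaptation_gain", 0.25)),
        )
        keystrokes = simulate_keystroke_session(design, params)
        write_keystrokes(keystrokes, self.out_dir / "keystrokes.csv")

        mode = cfg.get("mode", "phase")
        if mode == "phase":
            kappa = _tupleize_kappa(cfg.get("kappa", {}), by_segment=True)
            for band in self.config["bands"]:
                self.sessions[band] = simulate_envelope_phase_session(
                    n_pairs=n_pairs, trials_per_cell=tpc,
                    kappa_by_segment=kappa,
                    sfreq=float(cfg.get("sfreq", 50.0)), seed=seed,
                    coupling_mode=cfg.get("coupling_mode", "dyadic"),
                    phase_drift=float(cfg.get("phase_drift", 1.0)),
                )
        elif mode == "eeg":
            params = SimParams(
                n_pairs=n_pairs, trials_per_cell=tpc,
                sfreq=float(cfg.get("sfreq", 250.0)), rng_seed=seed,
                modulation_depth=float(cfg.get("modulation_depth", 0.8)),
                coupling_kappa=_tupleize_kappa(cfg.get("kappa", {})),
                bands=tuple(self.config["bands"]),
                noise_scale=float(cfg.get("noise_scale", 0.3)),
                motor_noise_sigma=float(cfg.get("motor_noise_sigma", 10.0)),
                anticipation_bias=float(cfg.get("anticipation_bias", 2.0)),
                adaptation_gain=float(cfg.get("adaptation_gain", 0.25)),
            )
            self.epochs_by_pair = []
            for pair, sub in design.groupby("pair"):
                ep = simulate_dual_eeg(sub.reset_index(drop=True), params)
                ep.save(self.out_dir / f"epochs_pair{pair:02d}.h5")
                self.epochs_by_pair.append(ep)
            for band in self.config["bands"]:
                self.sessions[band] = [
                    _epochs_to_phase_session(ep, band)
                    for ep in self.epochs_by_pair
                ]
        else:
            raise ValueError(f"unknown sim mode {mode!r}")

    def stage_behavior(self):
        design = pd.read_csv(self.out_dir / "design.csv")
        session = pd.read_csv(self.out_dir / "keystrokes.csv")
        measures = bhv.trial_measures(session, design)
        measures.to_csv(self.out_dir / "behavior_trials.tsv", sep="\t",
                        index=False)
        bhv.condition_summary(measures).to_csv(
            self.out_dir / "behavior_conditions.tsv", sep="\t", index=False)
        anovas = []
        for outcome in ("adaptation_z", "asynchrony_first_half_s",
                        "asynchrony_second_half_s", "entry_asynchrony_s",
                        "iki_difference_s"):
            try:
                anovas.append(bhv.behavior_anova(measures, outcome))
            except (ValueError, KeyError):
                continue          # incomplete cells at tiny demo scales
        if anovas:
            pd.concat(anovas, ignore_index=True).to_csv(
                self.out_dir / "behavior_anova.tsv", sep="\t", index=False)
        self.behavior = measures

    def stage_ibs(self):
        self._require_sessions()
        self.plv_data = {}
        for band, sessions in self.sessions.items():
            for roi in self.config["rois"]:
                data = ctl.session_plv_data(
                    sessions, self.grid,
                    roi if sessions[0].theta1.ndim == 3 else None)
                self.plv_data[(band, roi)] = data
                np.savez(
                    self.out_dir / f"plv_{band}_{roi}.npz",
                    centers=self.grid.centers,
                    **{f"pair{_i:02d}_values": v for _i, (v, _) in enumerate(data)},
                    **{f"pair{_i:02d}_cells": c for _i, (_, c) in enumerate(data)},
                )

    def stage_cluster(self):
        reports = []
        self.cluster_results = {}
        for (band, roi), data in self._require_plv().items():
            res = permutation_test(data, self.perm)
            self.cluster_results[(band, roi)] = res
            reports.append(cluster_report(res, self.grid, band, roi, "real"))
        table = (pd.concat(reports, ignore_index=True) if reports
                 else pd.DataFrame())
        table.to_csv(self.out_dir / "clusters.tsv", sep="\t", index=False)
        with open(self.out_dir / "clusters.json", "w") as f:
            json.dump(table.to_dict(orient="records"), f, indent=1)

    def stage_controls(self):
        self._require_sessions()
        cfg = self.config.get("controls", {})
        seed = stage_seed(self.config["seed"], "controls")
        reports = []
        baselines = {}
        for band, sessions in self.sessions.items():
            roi = self.config["rois"][0]
            roi_arg = roi if sessions[0].theta1.ndim == 3 else None
            base = np.stack([
                _roi_reduce(ctl.baseline_plv(
                    s, self.grid, n_rep=int(cfg.get("baseline_reps", 20)),
                    seed=seed + i), s, roi)
                for i, s in enumerate(sessions)
            ])
            baselines[band] = base
            np.savez(self.out_dir / f"baseline_plv_{band}.npz",
                     baseline=base, centers=self.grid.centers)
            res = ctl.surrogate_cluster_analysis(
                sessions, self.perm, self.grid, seed=None, roi=roi_arg)
            reports.append(cluster_report(res, self.grid, band, roi,
                                          "surrogate"))
        self.baselines = baselines
        table = (pd.concat(reports, ignore_index=True) if reports
                 else pd.DataFrame())
        table.to_csv(self.out_dir / "surrogate_clusters.tsv", sep="\t",
                     index=False)

    def stage_brainbehavior(self):
        cfg = self.config.get("brain_behavior", {})
        if not hasattr(self, "behavior"):
            self.stage_behavior()
        plv_data = self._require_plv()
        band = self.config["bands"][0]
        roi = self.config["rois"][0]
        data = plv_data[(band, roi)]
        lo, hi = cfg.get("window", [6.7, 9.3])
        centers = self.grid.centers
        wmask = (centers >= lo + self.grid.width / 2 - 1e-9) & \
                (centers <= hi - self.grid.width / 2 + 1e-9)
        design = pd.read_csv(self.out_dir / "design.csv")
        rows = []
        for (values, cells), (pair, sub) in zip(data, design.groupby("pair")):
            sub = sub.sort_values("trial")
            pred = values[:, wmask].mean(axis=1)
            for trial_pos, (_, drow) in enumerate(sub.iterrows()):
                rows.append({"pair": pair, "trial": drow["trial"],
                             "plv": pred[trial_pos]})
        table = pd.merge(pd.DataFrame(rows), self.behavior,
                         on=["pair", "trial"])
        table = table[table["valid"]]
        reports = []
        for outcome in cfg.get("linear_outcomes", []):
            reports.append(fit_linear_mixed(table, outcome))
        for outcome in cfg.get("logistic_outcomes", []):
            reports.append(fit_logistic_mixed(table, outcome))
        with open(self.out_dir / "brain_behavior.json", "w") as f:
            json.dump(reports, f, indent=1)
        self.brain_behavior = reports

    # -- helpers -------------------------------------------------------
    def _require_sessions(self):
        if not self.sessions:
            self.stage_simulate()
        return self.sessions

    def _require_plv(self):
        if not hasattr(self, "plv_data"):
            self.stage_ibs()
        return self.plv_data

    def write_manifest(self, stages) -> dict:
        manifest = {
            "config": self.config,
            "stages_run": list(stages),
            "stage_seeds": {s: stage_seed(self.config["seed"], s)
                            for s in STAGES},
            "timings_s": self.timings,
            "artifacts": {
                p.name: _hash_file(p)
                for p in sorted(self.out_dir.iterdir())
                if p.is_file() and p.name != "manifest.json"
            },
        }
        with open(self.out_dir / "manifest.json", "w") as f:
            json.dump(manifest, f, indent=1, default=str)
        return manifest


def _roi_reduce(baseline, session: PhaseSession, roi: str):
    """ROI-average a channel-resolved baseline curve; pass ROI-level through."""
    if baseline.ndim == 1:
        return baseline
    from .montage import roi_indices
    return baseline[roi_indices(roi, session.ch_names)].mean(axis=0)


def _epochs_to_phase_session(epochs, band: str) -> PhaseSession:
    """Envelope phases of one pair's epochs, channel-resolved."""
    thetas = []
    for data in (epochs.data1, epochs.data2):
        env = band_envelope(data, band, epochs.sfreq)
        thetas.append(envelope_phase(env, epochs.sfreq))
    cells = np.array([
        cell_index(r["tempo_condition"], r["familiarity"])
        for _, r in epochs.conditions.iterrows()
    ])
    return PhaseSession(
        pair=int(epochs.conditions["pair"].iloc[0]),
        theta1=thetas[0], theta2=thetas[1],
        times=epochs.times, sfreq=epochs.sfreq, cells=cells,
        design=epochs.conditions, ch_names=list(epochs.ch_names),
    )


def _tupleize_kappa(kappa_cfg: dict, by_segment: bool = False) -> dict:
    """Parse YAML kappa maps: segment-> or 'band/segment'-> value."""
    out = {}
    for key, val in (kappa_cfg or {}).items():
        if by_segment:
            out[key] = val
        else:
            if "/" not in str(key):
                raise ValueError(
                    f"eeg-mode kappa keys are 'band/segment', got {key!r}")
            band, segment = str(key).split("/", 1)
            out[(band, segment)] = val
    return out


def run(config, out_dir, stages=None) -> dict:
    """Execute a pipeline run; returns the manifest."""
    return Run(config, out_dir).run(stages)
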