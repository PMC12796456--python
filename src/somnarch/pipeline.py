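"""End-to-end orchestration: simulate/load -> artifact marking ->
smoothing -> phase split -> architecture metrics -> spindles ->
spectra, with a manifest for provenance and byte-reproducible outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .architecture import (bout_table, median_bout_duration, state_profile,
                           state_proportions, transitions)
from .errors import (ConfigMismatchError, NoNremsError, NoValidEpochsError,
                     PipelineError, UndefinedMetricError, ValidationError)
from .hypno import PHASES, SmoothingRule, mark_artifacts, smooth_hypnogram
from .io import NREM, VIGILANCE_STATES, Hypnogram, read_hypnogram, read_recording
from .sim import SimulationConfig, simulate_recording
from .spectral import (DEFAULT_BANDS, band_power, epoch_psd, group_psd_ci,
                       group_ttest, normalize_psd, spectral_auc)
from .spindles import SpindleParams, detect_spindles, spindle_stats

logger = logging.getLogger(__name__)

_CSV_FLOAT = "%.10g"


@dataclass
class RunConfig:
    """One analysis run: either a simulation block or explicit inputs.

    ``inputs`` rows are ``{"recording": path, "hypnogram": path}``; with
    a ``simulation`` block, ``n_animals`` recordings are generated from
    seeds derived from ``seed``.
    """

    out_dir: str
    simulation: dict | None = None
    inputs: list[dict] | None = None
    n_animals: int = 1
    epoch_s: float = 4.0
    min_run: int = 3
    artifact_sd: float = 15.0
    spindle: dict = field(default_factory=dict)
    bands: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_BANDS.items()})
    bootstrap_b: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.simulation is None) == (self.inputs is None):
            raise ValidationError(
                "config must provide exactly one of 'simulation' or 'inputs'"
            )
        if self.inputs is not None:
            missing = [row for row in self.inputs
                       if not (Path(row["recording"]).exists()
                               and Path(row["hypnogram"]).exists())]
            if missing:
                raise ValidationError(f"input files not found: {missing}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)

    def to_dict(self) -> dict:
        return {
            "out_dir": str(self.out_dir), "simulation": self.simulation,
            "inputs": self.inputs, "n_animals": self.n_animals,
            "epoch_s": self.epoch_s, "min_run": self.min_run,
            "artifact_sd": self.artifact_sd, "spindle": self.spindle,
            "bands": self.bands, "bootstrap_b": self.bootstrap_b,
            "seed": self.seed,
        }

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def _stage(name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
        return wrapped
    return deco


def _load_animals(cfg: RunConfig):
    """Yield (animal_id, recording, raw_hypnogram) pairs."""
    if cfg.simulation is not None:
        sim_cfg = SimulationConfig.from_dict(cfg.simulation)
        for i in range(cfg.n_animals):
            seed_i = (cfg.seed + 1000 * i) % (2**31 - 1)
            rec, hyp, _truth = simulate_recording(sim_cfg, seed_i)
            yield f"sim{i:02d}", rec, hyp
    else:
        for i, row in enumerate(cfg.inputs):
            rec = read_recording(row["recording"])
            hyp = read_hypnogram(row["hypnogram"], epoch_s=cfg.epoch_s,
                                 zt_start=rec.zt_start)
            yield row.get("id", f"animal{i:02d}"), rec, hyp


def run_pipeline(cfg: RunConfig) -> Path:
    """Run every stage for every animal and write the report bundle.

    Outputs: ``metrics.csv`` (tidy: animal, phase, state, metric,
    value), ``spindles.csv`` (one row per event), ``psd.csv`` (group
    median spectra with CIs per state and phase), ``profile.csv``
    (2-h state time-course), and ``manifest.json``.
    Deterministic for fixed (config, seed).
    """
    out_dir = Path(cfg.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rule = SmoothingRule(min_run=cfg.min_run, epoch_s=cfg.epoch_s)
    spindle_params = SpindleParams(**cfg.spindle) if cfg.spindle else SpindleParams()
    bands = {k: tuple(v) for k, v in cfg.bands.items()}

    metric_rows, spindle_rows, psd_rows = [], [], []
    smoothed_by_animal: dict[str, Hypnogram] = {}
    norm_psds: dict[tuple[str, str], dict[str, np.ndarray]] = {}
    freqs_ref = None

    for animal, rec, raw_hyp in _load_animals(cfg):
        logger.info("processing %s (%.1f h at %g Hz)", animal, rec.duration_h, rec.fs)
        hyp = _stage("mark_artifacts")(mark_artifacts)(rec, raw_hyp, cfg.artifact_sd)
        hyp = _stage("smooth")(smooth_hypnogram)(hyp, rule)
        smoothed_by_animal[animal] = hyp

        for phase in PHASES:
            try:
                props = state_proportions(hyp, phase)
            except NoValidEpochsError:
                continue
            for s, v in props.items():
                metric_rows.append((animal, phase, s, "proportion", v))

            bouts = bout_table(hyp, phase)
            for s in VIGILANCE_STATES:
                try:
                    metric_rows.append((animal, phase, s, "median_bout_s",
                                        median_bout_duration(bouts, s)))
                except UndefinedMetricError:
                    metric_rows.append((animal, phase, s, "median_bout_s", np.nan))

            trans = transitions(hyp, phase)
            for a in VIGILANCE_STATES:
                for b in VIGILANCE_STATES:
                    if a == b:
                        continue
                    metric_rows.append(
                        (animal, phase, f"{a}>{b}", "transitions_per_h",
                         float(trans.rates_per_h.loc[a, b]))
                    )

        try:
            events = _stage("spindles")(detect_spindles)(rec.eeg, hyp, rec.fs,
                                                         spindle_params)
        except PipelineError as exc:
            if not isinstance(exc.__cause__, NoNremsError):
                raise
            logger.info("%s: no NREMS epochs; skipping spindle metrics", animal)
            events = []
        for ev in events:
            spindle_rows.append((animal, ev.start_s, ev.duration_s,
                                 ev.peak_cubed_rms, ev.normalized_amplitude))
        for phase in PHASES:
            try:
                summary = spindle_stats(events, hyp, phase)
            except UndefinedMetricError:
                continue
            metric_rows += [
                (animal, phase, NREM, "spindle_amount", float(summary.amount)),
                (animal, phase, NREM, "spindle_density_per_min", summary.density_per_min),
                (animal, phase, NREM, "spindle_median_duration_s", summary.median_duration_s),
                (animal, phase, NREM, "spindle_median_norm_amplitude",
                 summary.median_normalized_amplitude),
            ]

        for phase in PHASES:
            for state in VIGILANCE_STATES:
                try:
                    freqs, _per_ep, mean_psd = epoch_psd(rec.eeg, hyp, rec.fs,
                                                         state, phase)
                except NoValidEpochsError:
                    continue
                norm = normalize_psd(mean_psd, freqs)
                freqs_ref = freqs
                norm_psds.setdefault((state, phase), {})[animal] = norm
                for name, power in band_power(norm, freqs, bands).items():
                    metric_rows.append((animal, phase, state,
                                        f"rel_power_{name}", power))

    for (state, phase), per_animal in sorted(norm_psds.items()):
        stack = np.vstack(list(per_animal.values()))
        result = group_psd_ci(stack, freqs_ref, n_boot=cfg.bootstrap_b, seed=cfg.seed)
        for f, m, lo, hi in zip(result.frequencies, result.median,
                                result.ci_lo, result.ci_hi):
            psd_rows.append((state, phase, f, m, lo, hi, result.n_animals))

    metrics = pd.DataFrame(metric_rows,
                           columns=["animal", "phase", "state", "metric", "value"])
    metrics.to_csv(out_dir / "metrics.csv", index=False, float_format=_CSV_FLOAT)
    pd.DataFrame(spindle_rows, columns=[
        "animal", "start_s", "duration_s", "peak_cubed_rms", "normalized_amplitude",
    ]).to_csv(out_dir / "spindles.csv", index=False, float_format=_CSV_FLOAT)
    pd.DataFrame(psd_rows, columns=[
        "state", "phase", "frequency_hz", "median", "ci_lo", "ci_hi", "n_animals",
    ]).to_csv(out_dir / "psd.csv", index=False, float_format=_CSV_FLOAT)

    hyps = list(smoothed_by_animal.values())
    if hyps:
        profile = state_profile(hyps, bin_h=2.0, n_boot=cfg.bootstrap_b, seed=cfg.seed)
        profile.to_csv(out_dir / "profile.csv", index=False, float_format=_CSV_FLOAT)

    manifest = {
        "somnarch_version": __version__,
        "config": cfg.to_dict(),
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "n_animals": len(smoothed_by_animal),
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return out_dir


_COMPAT_KEYS = ("epoch_s", "min_run", "bands", "spindle")


def compare_groups(dir_a: str | Path, dir_b: str | Path, alpha: float = 0.05,
                   n_boot: int = 1000, seed: int = 0) -> pd.DataFrame:
    """Per-metric group comparison of two completed runs.

    For every (phase, state, metric) present in both runs, a two-sample
    t-test and the ROC-AUC of group A over B are computed across
    animals; p-values are reported raw with an ``alpha`` significance
    flag (no multiplicity correction), and metrics with n < 2 in either
    group are marked undefined.
    """
    dir_a, dir_b = Path(dir_a), Path(dir_b)
    man_a = json.loads((dir_a / "manifest.json").read_text())
    man_b = json.loads((dir_b / "manifest.json").read_text())
    diffs = {
        key: (man_a["config"].get(key), man_b["config"].get(key))
        for key in _COMPAT_KEYS
        if man_a["config"].get(key) != man_b["config"].get(key)
    }
    if diffs:
        raise ConfigMismatchError(f"incompatible run configs: {diffs}")

    metrics_a = pd.read_csv(dir_a / "metrics.csv")
    metrics_b = pd.read_csv(dir_b / "metrics.csv")
    keys = ["phase", "state", "metric"]
    rows = []
    grouped_b = metrics_b.groupby(keys)["value"]
    for key, sub_a in metrics_a.groupby(keys)["value"]:
        try:
            sub_b = grouped_b.get_group(key)
        except KeyError:
            continue
        a = sub_a.dropna().to_numpy()
        b = sub_b.dropna().to_numpy()
        row = dict(zip(keys, key))
        row.update({"n_a": a.size, "n_b": b.size})
        if a.size >= 2 and b.size >= 2:
            t, p = group_ttest(a, b)
            auc = spectral_auc(a, b, n_boot=n_boot, seed=seed)
            row.update({
                "mean_a": a.mean(), "mean_b": b.mean(), "t": t, "p": p,
                "significant": bool(p < alpha),
                "auc": auc.auc, "auc_lo": auc.ci_lo, "auc_hi": auc.ci_hi,
            })
        else:
            row.update({
                "mean_a": a.mean() if a.size else np.nan,
                "mean_b": b.mean() if b.size else np.nan,
                "t": np.nan, "p": np.nan, "significant": False,
                "auc": np.nan, "auc_lo": np.nan, "auc_hi": np.nan,
            })
        rows.append(row)
    return pd.DataFrame(rows)
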