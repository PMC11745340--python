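"""File formats and the simulate → fit → interpret → compare pipeline.

All event/covariate/curve artifacts are CSV for auditability; models and
run manifests are JSON.  Schemas:

- ``events.csv``:     subject_id, time_s
- ``hypnogram.csv``:  epoch_index, stage
- ``covariates.csv``: time_s, phase_rad, sop_norm

Every pipeline stage writes a JSON manifest naming the command, config
hash, seed and package version that produced its artifacts, so any stage
can be reproduced bit-for-bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .events import STAGES, CovariateSeries, EventTrain, Hypnogram, assemble_covariates
from .model import (
    SPEC_TOKENS,
    FittedModel,
    ModelSpec,
    deviance_fractions,
    fit_spec,
    likelihood_ratio_test,
    synergy_index,
    time_rescaling_ks,
)
from .splines import HistoryBasis
from .interpret import (
    features_with_infraslow,
    history_modulation_curve,
    phase_tuning,
)
from .population import feature_group_tests, global_permutation_curve_test
from .synthetic import paper_like_scenario, simulate_night

logger = logging.getLogger(__name__)

PIPELINE_COMMANDS = (
    "simulate",
    "fit",
    "interpret",
    "gof",
    "decompose",
    "synergy",
    "population",
)


@dataclass
class RecordingBundle:
    """One recording: events + hypnogram + SO covariates (+ provenance)."""

    subject_id: str
    train: EventTrain
    hypnogram: Hypnogram
    phase_t: np.ndarray | None = None
    phase: np.ndarray | None = None
    sop: np.ndarray | None = None
    eeg_ref: dict | None = None        # {"path":..., "channel":...}
    meta: dict | None = None

    def __post_init__(self) -> None:
        if self.phase is None and self.eeg_ref is None:
            raise ValueError(
                "bundle needs precomputed covariates or an EEG reference"
            )

    def covariates(self, dt_s: float = 0.1) -> CovariateSeries:
        return assemble_covariates(
            self.train,
            self.hypnogram,
            self.phase,
            self.sop,
            dt_s,
            phase_t=self.phase_t,
            sop_t=self.phase_t,
        )


def read_edf_signal(path, channel: str):
    """EDF adapter: returns (samples, fs_hz, channel label) via mne."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF ingestion requires the optional 'mne' package") from exc
    raw = mne.io.read_raw_edf(path, include=[channel], preload=True, verbose="error")
    data = raw.get_data(picks=[channel])[0]
    return data, float(raw.info["sfreq"]), channel


# --------------------------------------------------------------------------
# bundle round-trip


def write_bundle(bundle: RecordingBundle, out_dir) -> dict:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "events": out / "events.csv",
        "hypnogram": out / "hypnogram.csv",
        "covariates": out / "covariates.csv",
        "meta": out / "bundle.json",
    }
    pd.DataFrame(
        {"subject_id": bundle.subject_id, "time_s": bundle.train.times}
    ).to_csv(paths["events"], index=False)
    pd.DataFrame(
        {
            "epoch_index": np.arange(len(bundle.hypnogram.stages)),
            "stage": list(bundle.hypnogram.stages),
        }
    ).to_csv(paths["hypnogram"], index=False)
    if bundle.phase is not None:
        pd.DataFrame(
            {
                "time_s": bundle.phase_t,
                "phase_rad": bundle.phase,
                "sop_norm": bundle.sop,
            }
        ).to_csv(paths["covariates"], index=False, float_format="%.6f")
    meta = {
        "subject_id": bundle.subject_id,
        "duration_s": bundle.train.duration_s,
        "epoch_s": bundle.hypnogram.epoch_s,
        "eeg_ref": bundle.eeg_ref,
        "meta": bundle.meta or {},
        "version": __version__,
    }
    paths["meta"].write_text(json.dumps(meta, indent=1))
    return {k: str(v) for k, v in paths.items()}


def read_bundle(bundle_dir) -> RecordingBundle:
    """Read and validate a bundle directory written by :func:`write_bundle`."""
    d = Path(bundle_dir)
    for name in ("events.csv", "hypnogram.csv", "bundle.json"):
        if not (d / name).exists():
            raise FileNotFoundError(f"missing bundle file: {d / name}")
    meta = json.loads((d / "bundle.json").read_text())
    ev = pd.read_csv(d / "events.csv", float_precision="round_trip")
    for col in ("subject_id", "time_s"):
        if col not in ev.columns:
            raise ValueError(f"events.csv missing column {col!r}")
    times = ev["time_s"].to_numpy(dtype=float)
    if times.size and times.min() < 0:
        raise ValueError("events.csv contains a negative time")
    if np.any(np.diff(times) <= 0):
        raise ValueError("events.csv times must be strictly increasing")
    hyp = pd.read_csv(d / "hypnogram.csv")
    for col in ("epoch_index", "stage"):
        if col not in hyp.columns:
            raise ValueError(f"hypnogram.csv missing column {col!r}")
    bad = sorted(set(hyp["stage"]) - set(STAGES))
    if bad:
        raise ValueError(f"hypnogram.csv has invalid stage label(s): {bad}")
    train = EventTrain(
        times=times,
        duration_s=float(meta["duration_s"]),
        subject_id=str(meta["subject_id"]),
    )
    hypnogram = Hypnogram(
        stages=tuple(hyp["stage"]), epoch_s=float(meta["epoch_s"])
    )
    phase_t = phase = sop = None
    if (d / "covariates.csv").exists():
        cv = pd.read_csv(d / "covariates.csv", float_precision="round_trip")
        for col in ("time_s", "phase_rad", "sop_norm"):
            if col not in cv.columns:
                raise ValueError(f"covariates.csv missing column {col!r}")
        phase_t = cv["time_s"].to_numpy(float)
        phase = cv["phase_rad"].to_numpy(float)
        sop = cv["sop_norm"].to_numpy(float)
    return RecordingBundle(
        subject_id=str(meta["subject_id"]),
        train=train,
        hypnogram=hypnogram,
        phase_t=phase_t,
        phase=phase,
        sop=sop,
        eeg_ref=meta.get("eeg_ref"),
        meta=meta.get("meta"),
    )


# --------------------------------------------------------------------------
# model serialization


def model_to_json(model: FittedModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=1))


def model_from_json(path) -> FittedModel:
    d = json.loads(Path(path).read_text())
    spec = ModelSpec(**d["spec"])
    basis = (
        HistoryBasis(tuple(d["history_knots"]))
        if d.get("history_knots")
        else None
    )
    labels = d["covariance"]["labels"]
    # term map is re-derivable from labels
    terms: dict = {}
    for lab in labels:
        key = lab.split("[")[0] if "[" in lab else lab
        key = {"hist": "history", "stagephase": "stage_phase",
               "sopphase_cos": "sop_phase", "sopphase_sin": "sop_phase",
               "phase_cos": "phase", "phase_sin": "phase",
               "sop2": "sop"}.get(key, key)
        terms.setdefault(key, []).append(lab)
    return FittedModel(
        params=pd.Series(d["coefficients"]),
        cov_params=pd.DataFrame(
            d["covariance"]["matrix"], index=labels, columns=labels
        ),
        log_likelihood=d["log_likelihood"],
        deviance=d["deviance"],
        n_events=d["n_events"],
        n_bins=d["n_bins"],
        spec=spec,
        basis=basis,
        terms=terms,
        dropped=d.get("dropped_columns", []),
        data_key=(d["n_bins"], d["n_events"], None),
    )


# --------------------------------------------------------------------------
# pipeline driver


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_manifest(out: Path, command: str, config: dict, seed, outputs) -> None:
    manifest = {
        "command": command,
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "version": __version__,
        "outputs": [str(p) for p in outputs],
    }
    (out / f"manifest_{command}.json").write_text(json.dumps(manifest, indent=1))


def run_pipeline(command: str, config: dict, out_dir=".", seed=None) -> dict:
    """Run one pipeline stage and write its artifacts plus a manifest.

    Commands: simulate | fit | interpret | gof | decompose | synergy |
    population.  ``config`` is a JSON-compatible dict; ``seed`` overrides
    any seed in the config.  Returns a dict of artifact paths (and, for
    convenience, key in-memory results under non-path keys).
    """
    if command not in PIPELINE_COMMANDS:
        raise ValueError(
            f"unknown command {command!r}; choose from {PIPELINE_COMMANDS}"
        )
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0)) if seed is None else int(seed)
    result = {}

    if command == "simulate":
        scen = paper_like_scenario(config.get("scenario", "paper_default"), seed)
        night = simulate_night(scen, seed=seed)
        bundle = RecordingBundle(
            subject_id=config.get("subject_id", scen.name),
            train=night.train,
            hypnogram=night.hypnogram,
            phase_t=night.so.t,
            phase=night.so.phase,
            sop=night.so.sop,
            meta={"scenario": scen.to_dict(), "seed": seed},
        )
        result.update(write_bundle(bundle, out))
        logger.info(
            "simulated %s: %d events in %.1f h",
            scen.name,
            night.train.n_events,
            night.train.duration_s / 3600,
        )
    elif command == "fit":
        bundle = read_bundle(config["bundle_dir"])
        dt = float(config.get("dt_s", 0.1))
        token = config.get("spec", "stage+phase+interaction+history15")
        model = fit_spec(bundle.covariates(dt), token)
        path = out / "model.json"
        model_to_json(model, path)
        result["model"] = str(path)
        result["n_events"] = model.n_events
        logger.info("fit %s: LL=%.1f, %d events", token, model.log_likelihood,
                    model.n_events)
    elif command == "interpret":
        model = model_from_json(config["model"])
        if model.spec.history != "none":
            curve = history_modulation_curve(model)
            curve.as_frame().to_csv(out / "history_curve.csv", index=False)
            feats = features_with_infraslow(curve)
            pd.DataFrame([feats.as_dict()]).to_csv(
                out / "history_features.csv", index=False
            )
            result["history_curve"] = str(out / "history_curve.csv")
            result["history_features"] = str(out / "history_features.csv")
        if "phase_cos" in model.params.index:
            contexts = ["all"]
            if "stage_phase" in model.terms:
                contexts += list(STAGES)
            rows = []
            for c in contexts:
                pc = phase_tuning(model, None if c == "all" else c)
                rows.append(
                    {
                        "context": pc.context,
                        "magnitude": pc.magnitude,
                        "phi_pref_rad": pc.phi_pref,
                        "ci_low": pc.ci[0],
                        "ci_high": pc.ci[1],
                        "no_preferred_phase": pc.no_preferred_phase,
                    }
                )
            pd.DataFrame(rows).to_csv(out / "phase_coupling.csv", index=False)
            result["phase_coupling"] = str(out / "phase_coupling.csv")
    elif command == "gof":
        bundle = read_bundle(config["bundle_dir"])
        model = model_from_json(config["model"])
        cov = bundle.covariates(model.spec.dt_s)
        gof = time_rescaling_ks(model, bundle.train, cov)
        path = out / "gof.json"
        path.write_text(
            json.dumps(
                {"ks_statistic": gof.ks_statistic, "n": gof.n, "pass_05": gof.pass_05}
            )
        )
        result["gof"] = str(path)
    elif command == "decompose":
        bundle = read_bundle(config["bundle_dir"])
        cov = bundle.covariates(float(config.get("dt_s", 0.1)))
        chain_tokens = config.get(
            "chain",
            ["null", "stage", "stage+phase+interaction",
             "stage+phase+interaction+history15"],
        )
        chain = [fit_spec(cov, t) for t in chain_tokens]
        singles = {
            t: fit_spec(cov, t)
            for t in config.get("single_factors", ["stage", "phase", "history15"])
        }
        dec = deviance_fractions(
            chain, names=chain_tokens[1:], single_factor=singles
        )
        dec.as_frame().to_csv(out / "deviance_decomposition.csv", index=False)
        result["decomposition"] = str(out / "deviance_decomposition.csv")
        # reverse ordering (history first) is also reported
        rev_tokens = config.get(
            "chain_reversed",
            ["null", "history15", "stage+phase+interaction+history15"],
        )
        rev = [fit_spec(cov, t) for t in rev_tokens]
        deviance_fractions(rev, names=rev_tokens[1:]).as_frame().to_csv(
            out / "deviance_decomposition_history_first.csv", index=False
        )
        result["decomposition_history_first"] = str(
            out / "deviance_decomposition_history_first.csv"
        )
    elif command == "synergy":
        bundle = read_bundle(config["bundle_dir"])
        cov = bundle.covariates(float(config.get("dt_s", 0.1)))
        null = fit_spec(cov, config.get("null", "stage"))
        a = fit_spec(cov, config.get("model_a", "stage+phase"))
        b = fit_spec(cov, config.get("model_b", "stage+history15"))
        ab = fit_spec(cov, config.get("model_ab", "stage+phase+history15"))
        syn = synergy_index(null, a, b, ab)
        path = out / "synergy.json"
        path.write_text(
            json.dumps(
                {
                    "index": syn.index,
                    "gain_phase_bits_per_event": syn.gain_a,
                    "gain_history_bits_per_event": syn.gain_b,
                    "gain_joint_bits_per_event": syn.gain_joint,
                }
            )
        )
        result["synergy"] = str(path)
    elif command == "population":
        n = int(config.get("n_subjects", 8))
        scen_name = config.get("scenario", "paper_default")
        dt = float(config.get("dt_s", 0.1))
        rows, curves = [], []
        for i in range(n):
            scen = paper_like_scenario(scen_name, seed + i)
            night = simulate_night(scen, seed=seed + i)
            model = fit_spec(night.cov, "stage+phase+interaction+history15")
            curve = history_modulation_curve(model)
            feats = features_with_infraslow(curve)
            row = {"subject": f"S{i:03d}", **feats.as_dict()}
            row["group"] = "A" if i < n // 2 else "B"
            rows.append(row)
            curves.append(curve)
        feats_df = pd.DataFrame(rows)
        feats_df.to_csv(out / "population_features.csv", index=False)
        comp = feature_group_tests(
            feats_df.drop(columns=["subject"]), grouping="group"
        )
        comp.to_csv(out / "population_comparisons.csv", index=False)
        half = n // 2
        perm = global_permutation_curve_test(
            curves[:half], curves[half:], n_perm=499, seed=seed
        )
        pd.DataFrame(
            {
                "lag_s": curves[0].lags,
                "significant": perm.pointwise_mask.astype(int),
            }
        ).to_csv(out / "population_permutation_mask.csv", index=False)
        result["features"] = str(out / "population_features.csv")
        result["comparisons"] = str(out / "population_comparisons.csv")
        result["global_p"] = perm.global_p

    _write_manifest(out, command, config, seed,
                    [v for v in result.values() if isinstance(v, str)])
    result["manifest"] = str(out / f"manifest_{command}.json")
    return result
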