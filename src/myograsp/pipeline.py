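"""End-to-end pipeline plumbing: file formats, configuration, seeds,
logging, and the one-call reproduction of the six-object controller
comparison on synthetic data.

All randomness flows from three named seeds (generator, split, network
initialization); a run is reproducible from the serialized config alone.
Every artifact is plain text: CSV for sample streams (comma-separated,
header row, '.' decimal, UTF-8, LF) and JSON for profiles, models and
reports.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classifier as clf
from . import controller as ctl
from . import evaluation as ev
from . import preprocess as pp
from . import simulate as sim
from .poses import CLASS_ORDER, PoseClass

log = logging.getLogger("myograsp")


# ---------------------------------------------------------------------------
# readers / writers  (read(write(x)) == x for every pair)
# ---------------------------------------------------------------------------

def write_recording(recording: sim.EmgRecording, path: str | Path) -> None:
    df = pd.DataFrame(recording.samples,
                      columns=list(recording.acquisition.channel_names))
    df.insert(0, "time_s", recording.times)
    df["label"] = recording.label_codes()
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_recording(
    path: str | Path, acquisition: sim.AcquisitionConfig | None = None
) -> sim.EmgRecording:
    df = pd.read_csv(path)
    channels = [c for c in df.columns if c not in ("time_s", "label")]
    if acquisition is None:
        dt = np.diff(df["time_s"].to_numpy()[:2])
        fs = 1.0 / dt[0] if len(dt) else 2000.0
        acquisition = sim.AcquisitionConfig(
            sampling_rate=float(round(fs, 6)), channel_names=tuple(channels)
        )
    labels = [int(PoseClass.from_code(c)) for c in df["label"]]
    return sim.EmgRecording(
        acquisition=acquisition,
        samples=df[channels].to_numpy(),
        labels=np.array(labels, dtype=np.int8),
    )


def write_envelope(stream: pp.EnvelopeStream, path: str | Path) -> None:
    df = pd.DataFrame(stream.values, columns=list(stream.channel_names))
    df.insert(0, "time_s", stream.times)
    if stream.labels is not None:
        df["label"] = [CLASS_ORDER[i].code for i in stream.labels]
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_envelope(path: str | Path) -> pp.EnvelopeStream:
    df = pd.read_csv(path)
    channels = [c for c in df.columns if c not in ("time_s", "label")]
    t = df["time_s"].to_numpy()
    fs = 1.0 / (t[1] - t[0]) if len(t) > 1 else 2000.0
    labels = None
    if "label" in df.columns:
        labels = np.array([int(PoseClass.from_code(c)) for c in df["label"]],
                          dtype=np.int8)
    return pp.EnvelopeStream(
        values=df[channels].to_numpy(),
        sampling_rate=float(round(fs, 6)),
        labels=labels,
        channel_names=tuple(channels),
    )


def write_labels(labels: np.ndarray, rate: float, path: str | Path) -> None:
    df = pd.DataFrame({
        "time_s": np.arange(len(labels)) / rate,
        "label": [CLASS_ORDER[int(i)].code for i in labels],
    })
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def read_labels(path: str | Path) -> tuple[np.ndarray, float]:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy()
    fs = 1.0 / (t[1] - t[0]) if len(t) > 1 else 2000.0
    labels = np.array([int(PoseClass.from_code(c)) for c in df["label"]],
                      dtype=np.int8)
    return labels, float(round(fs, 6))


def write_commands(
    stream: ctl.PoseCommandStream, predicted: np.ndarray, path: str | Path
) -> None:
    event_samples = {e.sample for e in stream.events}
    df = pd.DataFrame({
        "time_s": stream.times,
        "predicted_label": [CLASS_ORDER[int(i)].code for i in predicted],
        "commanded_pose": [CLASS_ORDER[int(i)].code for i in stream.commands],
        "event_flag": [int(i in event_samples) for i in range(len(stream.commands))],
    })
    df.to_csv(path, index=False, lineterminator="\n", float_format="%.10g")


def write_mvic(mvic: pp.MvicProfile, channel_names: tuple[str, ...],
               path: str | Path) -> None:
    Path(path).write_text(json.dumps({
        "values": dict(zip(channel_names, mvic.values.tolist())),
        "method": mvic.method,
    }, indent=1), encoding="utf-8")


def read_mvic(path: str | Path) -> tuple[pp.MvicProfile, tuple[str, ...]]:
    d = json.loads(Path(path).read_text(encoding="utf-8"))
    names = tuple(d["values"].keys())
    return pp.MvicProfile(values=np.array([d["values"][k] for k in names]),
                          method=d.get("method", "unknown")), names


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to reproduce an end-to-end run."""

    acquisition: sim.AcquisitionConfig = field(default_factory=sim.AcquisitionConfig)
    protocol: sim.ProtocolSpec = field(default_factory=sim.ProtocolSpec)
    profile: sim.ActivationProfile = field(default_factory=sim.ActivationProfile)
    filter_spec: pp.FilterSpec = field(default_factory=pp.FilterSpec)
    split: clf.SplitSpec = field(default_factory=clf.SplitSpec)
    controller: ctl.ControllerConfig = field(default_factory=ctl.ControllerConfig)
    mvic_amplitude: float = 1.0          # raw signal units (amplified scale)
    severity: float = 0.0                # SCI degradation, 0 = healthy
    hidden_units: int = 10
    max_iterations: int = 500
    max_train_samples: int | None = 40000  # seeded subsample cap for SCG
    label_noise: float = 0.0             # extra i.i.d. noise on predicted labels
    generator_seed: int = 11
    split_seed: int = 23
    init_seed: int = 37

    def to_json(self) -> str:
        def enc(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if isinstance(obj, PoseClass):
                return obj.code
            if isinstance(obj, ctl.ControlMode):
                return obj.value
            if dataclasses.is_dataclass(obj):
                return {f.name: enc(getattr(obj, f.name))
                        for f in dataclasses.fields(obj)}
            if isinstance(obj, (list, tuple)):
                return [enc(x) for x in obj]
            return obj
        return json.dumps(enc(self), indent=1)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        proto = d.get("protocol", {})
        if "class_sequence" in proto:
            proto["class_sequence"] = tuple(
                PoseClass.from_code(c) for c in proto["class_sequence"])
        ctrl = d.get("controller", {})
        if "initial_pose" in ctrl:
            ctrl["initial_pose"] = PoseClass.from_code(ctrl["initial_pose"])
        if "mode" in ctrl:
            ctrl["mode"] = ctl.ControlMode(ctrl["mode"])
        acq = d.get("acquisition", {})
        if "channel_names" in acq:
            acq["channel_names"] = tuple(acq["channel_names"])
        return cls(
            acquisition=sim.AcquisitionConfig(**acq),
            protocol=sim.ProtocolSpec(**proto),
            profile=sim.ActivationProfile(**d.get("profile", {})),
            filter_spec=pp.FilterSpec(**d.get("filter_spec", {})),
            split=clf.SplitSpec(**d.get("split", {})),
            controller=ctl.ControllerConfig(**ctrl),
            **{k: d[k] for k in (
                "mvic_amplitude", "severity", "hidden_units", "max_iterations",
                "max_train_samples", "label_noise",
                "generator_seed", "split_seed", "init_seed") if k in d},
        )


def _subsample(dataset: clf.Dataset, cap: int | None, seed: int) -> clf.Dataset:
    if cap is None or len(dataset) <= cap:
        return dataset
    idx = np.sort(np.random.default_rng(seed).choice(len(dataset), cap,
                                                     replace=False))
    prov = dataset.provenance[idx] if dataset.provenance is not None else None
    return clf.Dataset(dataset.features[idx], dataset.targets[idx], prov)


# ---------------------------------------------------------------------------
# end-to-end run
# ---------------------------------------------------------------------------

def run_pipeline(config: PipelineConfig, outdir: str | Path | None = None) -> dict:
    """simulate -> preprocess -> train -> classify -> control (three modes)
    -> evaluate, on fully synthetic data.

    Returns a dict of in-memory artifacts plus a JSON-able ``report``;
    writes all intermediate files under ``outdir`` when given.
    """
    t_start = time.perf_counter()
    out = Path(outdir) if outdir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)

    seeds = np.random.SeedSequence(config.generator_seed).generate_state(4)
    seeds = [int(s % (2**31 - 1)) for s in seeds]
    profile = sim.degrade_for_sci(config.profile, config.severity)
    acq = config.acquisition
    artifacts: dict = {"config": config}

    def stage(name):
        log.info("stage %-12s t=%.1fs", name, time.perf_counter() - t_start)

    # --- calibration + training session -----------------------------------
    stage("simulate")
    calib, segments = sim.simulate_mvic_calibration(
        profile, acq, config.mvic_amplitude, seed=seeds[0])
    training = sim.simulate_session(
        config.protocol, profile, acq, config.mvic_amplitude, seed=seeds[1])

    stage("preprocess")
    mvic = pp.measure_mvic(calib, segments, spec=config.filter_spec)
    envelope = pp.preprocess_recording(training, mvic, spec=config.filter_spec)

    stage("train")
    dataset = clf.extract_dataset(envelope, trim=config.protocol.trim)
    train_set, test_set = clf.split_train_test(dataset, config.split)
    fit_set = _subsample(train_set, config.max_train_samples, config.split_seed)
    model = clf.train_mlp_scg(
        fit_set, hidden_units=config.hidden_units,
        max_iterations=config.max_iterations, seed=config.init_seed)
    cm_train = clf.confusion(model.predict(train_set.features), train_set.targets)
    cm_test = clf.confusion(model.predict(test_set.features), test_set.targets)

    # --- six-object dynamic grasping test ----------------------------------
    stage("classify")
    cues, truth = ev.six_object_scenario()
    truth_labels = ev.truth_label_stream(truth, acq.sampling_rate)
    test_rec = sim.synthesize_raw(truth_labels, profile, config.mvic_amplitude,
                                  acq, seed=seeds[2])
    test_env = pp.preprocess_recording(test_rec, mvic, spec=config.filter_spec)
    probs, predicted = clf.classify_stream(model, test_env)
    if config.label_noise > 0:
        predicted = ev.noisy_label_stream(predicted, config.label_noise,
                                          seed=seeds[3])

    stage("control")
    comparison = ev.compare_modes(predicted, cues, config.controller)

    stage("evaluate")
    report = {
        "seeds": {"generator": config.generator_seed,
                  "split": config.split_seed, "init": config.init_seed},
        "severity": config.severity,
        "mvic": dict(zip(acq.channel_names, mvic.values.tolist())),
        "filter_step_delay_s": pp.step_delay(config.filter_spec,
                                             acq.sampling_rate),
        "n_dataset": len(dataset),
        "n_train": len(train_set),
        "n_test": len(test_set),
        "train_accuracy_pct": cm_train.overall_accuracy,
        "test_accuracy_pct": cm_test.overall_accuracy,
        "per_class_test_accuracy_pct": {
            c.code: (None if np.isnan(a) else float(a))
            for c, a in zip(CLASS_ORDER, cm_test.per_class_accuracy)},
        "modes": comparison.summary(),
        "elapsed_s": time.perf_counter() - t_start,
    }
    artifacts.update(
        calibration=calib, training=training, mvic=mvic, envelope=envelope,
        dataset=dataset, model=model, confusion_train=cm_train,
        confusion_test=cm_test, test_envelope=test_env, predicted=predicted,
        probabilities=probs, cues=cues, comparison=comparison, report=report,
    )

    if out is not None:
        write_recording(training, out / "training_raw.csv")
        write_envelope(envelope, out / "training_envelope.csv")
        write_mvic(mvic, acq.channel_names, out / "mvic.json")
        (out / "model.json").write_text(model.to_json(), encoding="utf-8")
        write_labels(predicted, acq.sampling_rate, out / "predicted_labels.csv")
        for mode, stream in comparison.streams.items():
            write_commands(stream, predicted, out / f"commands_{mode}.csv")
        (out / "config.json").write_text(config.to_json(), encoding="utf-8")
        (out / "report.json").write_text(json.dumps(report, indent=1),
                                         encoding="utf-8")
    stage("done")
    return artifacts
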