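"""Configuration, file I/O and the end-to-end study pipeline.

File dialects (all UTF-8, comma-separated, ``.`` decimal, mandatory header):

* trial CSV - ``time_s`` plus one column per muscle in registry order;
* events JSON - cycle marks ``{"a": ..., "e": ...}`` in seconds;
* MVC CSV - ``muscle,reference``;
* jumps CSV - ``subject,protocol,time_point_min,jump_index,flight_time_s``.

:func:`run_pipeline` chains simulate -> preprocess -> synergy extraction ->
temporal features -> jump statistics, writes the group tables (weights,
temporal features, jump heights, VAF curves) plus a stats JSON, and returns
a manifest with content hashes so a run is verifiable and reproducible from
its seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import jumpstats, synthgen, timing
from .jumpstats import StatResult
from .muscles import MUSCLES, PROTOCOLS, TIME_POINTS_MIN
from .preprocess import PreprocessConfig, process_session
from .synergy import SynergyModel, match_synergies, nmf_fit, select_order
from .synthgen import GeneratorConfig, StudyDataset, Trial

__all__ = [
    "NmfConfig", "StatsConfig", "PipelineConfig", "RunManifest",
    "read_trial_csv", "write_trial_csv", "read_events_json",
    "write_events_json", "read_mvc_csv", "write_mvc_csv",
    "read_jumps_csv", "write_jumps_csv", "run_pipeline",
]

log = logging.getLogger("kicksyn")


# --------------------------------------------------------------------------
# configuration

@dataclass(frozen=True)
class NmfConfig:
    restarts: int = 20
    max_iter: int = 1000
    tol: float = 1e-6
    vaf_threshold: float = 0.90
    max_order: int = 10


@dataclass(frozen=True)
class StatsConfig:
    alpha: float = 0.05


@dataclass(frozen=True)
class PipelineConfig:
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    nmf: NmfConfig = field(default_factory=NmfConfig)
    timing_threshold: float = 0.20
    stats: StatsConfig = field(default_factory=StatsConfig)
    seed: int = 0
    out_dir: str = "results/run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        table = d["generator"]["jump_means_sds"]
        d["generator"]["jump_means_sds"] = {
            p: {int(t): list(ms) for t, ms in tab.items()}
            for p, tab in table.items()}
        d["generator"]["carrier_band"] = list(
            d["generator"]["carrier_band"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        gen = dict(d.get("generator", {}))
        if "jump_means_sds" in gen:
            gen["jump_means_sds"] = {
                p: {int(t): tuple(ms) for t, ms in tab.items()}
                for p, tab in gen["jump_means_sds"].items()}
        if "carrier_band" in gen:
            gen["carrier_band"] = tuple(gen["carrier_band"])
        return cls(
            generator=GeneratorConfig(**gen),
            preprocess=PreprocessConfig(**d.get("preprocess", {})),
            nmf=NmfConfig(**d.get("nmf", {})),
            timing_threshold=d.get("timing_threshold", 0.20),
            stats=StatsConfig(**d.get("stats", {})),
            seed=d.get("seed", 0),
            out_dir=d.get("out_dir", "results/run"))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))


@dataclass(frozen=True)
class RunManifest:
    config: dict
    version: str
    seed: int
    file_hashes: dict[str, str]
    selected_orders: dict[str, int]
    modal_order: int | None
    started_at: float
    finished_at: float


# --------------------------------------------------------------------------
# file I/O

def _parse_error(path, row, col, msg) -> ValueError:
    return ValueError(f"{path}: row {row}, column {col!r}: {msg}")


def write_trial_csv(path, trial: Trial,
                    muscle_labels: tuple[str, ...] = MUSCLES) -> Path:
    t = np.arange(trial.emg.shape[1]) / trial.sampling_rate
    df = pd.DataFrame({"time_s": t})
    for i, m in enumerate(muscle_labels):
        df[m] = trial.emg[i]
    path = Path(path)
    df.to_csv(path, index=False)
    return path


def read_trial_csv(path, sampling_rate: float = 2000.0,
                   muscle_labels: tuple[str, ...] = MUSCLES,
                   events_s: dict[str, float] | None = None) -> Trial:
    path = Path(path)
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise _parse_error(path, 0, "time_s", "missing required column")
    missing = [m for m in muscle_labels if m not in df.columns]
    if missing:
        raise _parse_error(path, 0, missing[0],
                           f"missing muscle column(s) {missing}")
    unknown = [c for c in df.columns
               if c != "time_s" and c not in muscle_labels]
    if unknown:
        raise _parse_error(path, 0, unknown[0],
                           f"unknown muscle label(s) {unknown}")
    for col in muscle_labels:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df.index[pd.to_numeric(df[col], errors="coerce").isna()][0]
            raise _parse_error(path, int(bad) + 2, col, "non-numeric cell")
    emg = df[list(muscle_labels)].to_numpy().T
    if events_s is None:
        dur = emg.shape[1] / sampling_rate
        events_s = {k: f * dur
                    for k, f in synthgen._EVENT_FRACTIONS.items()}
    return Trial(emg=emg, events_s=events_s, sampling_rate=sampling_rate)


def write_events_json(path, events_s: dict[str, float]) -> Path:
    path = Path(path)
    path.write_text(json.dumps(events_s, indent=1))
    return path


def read_events_json(path) -> dict[str, float]:
    path = Path(path)
    events = json.loads(path.read_text())
    missing = [k for k in ("a", "b", "c", "d", "e") if k not in events]
    if missing:
        raise ValueError(f"{path}: missing event mark(s) {missing}")
    stamps = [float(events[k]) for k in ("a", "b", "c", "d", "e")]
    if any(b <= a for a, b in zip(stamps, stamps[1:])):
        raise ValueError(f"{path}: event marks a-e must be strictly "
                         "increasing")
    return {k: float(events[k]) for k in ("a", "b", "c", "d", "e")}


def write_mvc_csv(path, mvc: dict[str, float]) -> Path:
    path = Path(path)
    pd.DataFrame({"muscle": list(mvc), "reference": list(mvc.values())}
                 ).to_csv(path, index=False)
    return path


def read_mvc_csv(path, muscle_labels: tuple[str, ...] = MUSCLES,
                 ) -> dict[str, float]:
    path = Path(path)
    df = pd.read_csv(path)
    for col in ("muscle", "reference"):
        if col not in df.columns:
            raise _parse_error(path, 0, col, "missing required column")
    table = dict(zip(df["muscle"], df["reference"].astype(float)))
    unknown = [m for m in table if m not in muscle_labels]
    if unknown:
        raise _parse_error(path, 0, unknown[0],
                           f"unknown muscle label(s) {unknown}")
    missing = [m for m in muscle_labels if m not in table]
    if missing:
        raise _parse_error(path, 0, missing[0],
                           f"missing muscle(s) {missing}")
    return table


def write_jumps_csv(path, jumps: pd.DataFrame) -> Path:
    path = Path(path)
    jumps.to_csv(path, index=False)
    return path


def read_jumps_csv(path) -> pd.DataFrame:
    path = Path(path)
    df = pd.read_csv(path)
    required = ("subject", "protocol", "time_point_min", "jump_index",
                "flight_time_s")
    for col in required:
        if col not in df.columns:
            raise _parse_error(path, 0, col, "missing required column")
    bad = df.index[~df["protocol"].isin(PROTOCOLS)]
    if len(bad):
        raise _parse_error(path, int(bad[0]) + 2, "protocol",
                           f"unknown protocol {df.loc[bad[0], 'protocol']!r};"
                           f" allowed: {list(PROTOCOLS)}")
    if (df["flight_time_s"] <= 0).any():
        row = df.index[df["flight_time_s"] <= 0][0]
        raise _parse_error(path, int(row) + 2, "flight_time_s",
                           "flight time must be positive")
    return df


def jumps_frame(dataset: StudyDataset) -> pd.DataFrame:
    """Long-format flight-time table for a generated dataset."""
    rows = []
    for subject in dataset.subjects:
        for protocol, session in subject.sessions.items():
            for ti, minutes in enumerate(session.time_points_min):
                for ji in range(session.flight_times_s.shape[1]):
                    rows.append({
                        "subject": subject.subject_id, "protocol": protocol,
                        "time_point_min": minutes, "jump_index": ji + 1,
                        "flight_time_s": session.flight_times_s[ti, ji]})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# pipeline

def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _stat_to_dict(r: StatResult) -> dict:
    d = dataclasses.asdict(r)
    d["comparison"] = list(r.comparison)
    return d


def _annotate(results: list[StatResult], means: dict[str, float],
              alpha: float) -> list[str]:
    """Human-readable post hoc verdicts such as ``"ESG > RBG"``."""
    notes = []
    for r in results:
        if r.p_adjusted < alpha and not r.degenerate:
            a, b = r.comparison
            hi, lo = (a, b) if means[a] >= means[b] else (b, a)
            notes.append(f"{hi} > {lo}")
    return notes


def _gated_posthoc(values: np.ndarray, labels: tuple[str, ...],
                   alpha: float) -> tuple[dict, list[str]]:
    """Omnibus test, then pairwise post hocs only when the omnibus rejects.

    Routed by the Shapiro-Wilk gate: parametric (one-way RM-ANOVA, paired t
    with Bonferroni) or non-parametric (Friedman, Wilcoxon with Holm).
    """
    cells = {lab: values[:, i] for i, lab in enumerate(labels)}
    gate = jumpstats.shapiro_gate(cells, alpha=alpha)
    means = {lab: float(values[:, i].mean()) for i, lab in enumerate(labels)}
    out: dict = {"parametric": gate.parametric,
                 "shapiro_p": gate.p_values,
                 "means": means}
    if gate.parametric:
        omnibus = jumpstats.one_way_rm_anova(values)
        out["omnibus"] = dataclasses.asdict(omnibus)
        significant = omnibus.p < alpha
    else:
        omnibus = jumpstats.friedman_test(values, labels=labels)
        out["omnibus"] = _stat_to_dict(omnibus)
        significant = (not omnibus.degenerate) and omnibus.p_raw < alpha
    notes: list[str] = []
    if significant:
        posthoc = jumpstats.posthoc_pairwise(values, labels=labels,
                                             parametric=gate.parametric)
        out["posthoc"] = [_stat_to_dict(r) for r in posthoc]
        notes = _annotate(posthoc, means, alpha)
    out["annotations"] = notes
    return out, notes


def _align_models(models: dict[str, SynergyModel],
                  reference_protocol: str) -> dict[str, SynergyModel]:
    """Reorder each model's synergies to match the reference protocol's."""
    ref = models[reference_protocol]
    aligned = {reference_protocol: ref}
    for protocol, model in models.items():
        if protocol == reference_protocol:
            continue
        perm = match_synergies(ref, model).permutation
        aligned[protocol] = dataclasses.replace(
            model, weights=model.weights[:, perm],
            coefficients=model.coefficients[perm])
    return aligned


def run_pipeline(config: PipelineConfig | None = None,
                 stages: tuple[str, ...] = ("synergy", "features", "jumps"),
                 ) -> RunManifest:
    """Run the study end to end on seeded synthetic data.

    Writes, under ``config.out_dir``: ``weights_table.csv`` (group mean +/- SD
    muscle weights per synergy and protocol, with post hoc annotations),
    ``features_table.csv`` (temporal activation features), ``jump_table.csv``
    (jump heights per protocol and time point with test results),
    ``vaf_curves.csv``, ``stats.json``, ``config.yaml``, ``run.log`` and
    ``manifest.json``.  Identical configurations reproduce identical output
    hashes (the manifest records them).
    """
    t0 = time.time()
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    log.info("conventions in force: normalization=%s, SST=uncentered, "
             "activation threshold=%.2f, VAF threshold=%.2f, alpha=%.3f",
             config.preprocess.normalization, config.timing_threshold,
             config.nmf.vaf_threshold, config.stats.alpha)

    gen = dataclasses.replace(config.generator, seed=config.seed)
    dataset = synthgen.generate_study(gen)
    labels = MUSCLES[:gen.n_muscles]
    alpha = config.stats.alpha
    files: dict[str, Path] = {}
    stats_report: dict = {"alpha": alpha}
    selected_orders: dict[str, int] = {}
    modal_order: int | None = None

    if "synergy" in stages or "features" in stages:
        nmf = config.nmf
        models: dict[str, dict[str, SynergyModel]] = {}
        vaf_rows = []
        for subject in dataset.subjects:
            per_protocol = {}
            for protocol in PROTOCOLS:
                D = process_session(subject.sessions[protocol],
                                    config.preprocess, labels)
                model = select_order(
                    D, threshold=nmf.vaf_threshold, max_order=nmf.max_order,
                    max_iter=nmf.max_iter, tol=nmf.tol,
                    seed=config.seed, restarts=nmf.restarts)
                per_protocol[protocol] = model
                selected_orders[f"{subject.subject_id}/{protocol}"] = \
                    model.order
                for order, vaf in model.vaf_curve.items():
                    vaf_rows.append({"subject": subject.subject_id,
                                     "protocol": protocol, "order": order,
                                     "vaf": vaf})
            models[subject.subject_id] = per_protocol

        modal_order = Counter(selected_orders.values()).most_common(1)[0][0]
        log.info("selected synergy orders: %s (modal %d)",
                 dict(Counter(selected_orders.values())), modal_order)
        for subject in dataset.subjects:
            for protocol in PROTOCOLS:
                model = models[subject.subject_id][protocol]
                if model.order != modal_order:
                    D = process_session(subject.sessions[protocol],
                                        config.preprocess, labels)
                    models[subject.subject_id][protocol] = nmf_fit(
                        D, modal_order, max_iter=nmf.max_iter, tol=nmf.tol,
                        seed=config.seed, restarts=nmf.restarts)
            models[subject.subject_id] = _align_models(
                models[subject.subject_id], PROTOCOLS[0])

        weight_rows = []
        feature_rows = []
        for subject in dataset.subjects:
            for protocol in PROTOCOLS:
                model = models[subject.subject_id][protocol]
                for k in range(model.order):
                    syn = f"SYN{k + 1}"
                    for mi, muscle in enumerate(labels):
                        weight_rows.append({
                            "subject": subject.subject_id,
                            "protocol": protocol, "synergy": syn,
                            "muscle": muscle,
                            "weight": model.weights[mi, k]})
                    if "features" in stages:
                        feats = timing.extract_features(
                            model.coefficients[k],
                            threshold=config.timing_threshold)
                        feature_rows.append({
                            "subject": subject.subject_id,
                            "protocol": protocol, "synergy": syn,
                            **feats.as_dict()})

        weights = pd.DataFrame(weight_rows)
        files["vaf_curves"] = out / "vaf_curves.csv"
        pd.DataFrame(vaf_rows).to_csv(files["vaf_curves"], index=False)

        # group table + per-(muscle, synergy) protocol comparison
        weight_stats = {}
        table_rows = []
        n_subjects = len(dataset.subjects)
        for syn in sorted(weights["synergy"].unique()):
            for muscle in labels:
                sub = weights[(weights.synergy == syn)
                              & (weights.muscle == muscle)]
                wide = sub.pivot(index="subject", columns="protocol",
                                 values="weight")[list(PROTOCOLS)]
                row = {"muscle": muscle, "synergy": syn}
                for protocol in PROTOCOLS:
                    row[f"{protocol}_mean"] = wide[protocol].mean()
                    row[f"{protocol}_sd"] = wide[protocol].std(ddof=1)
                notes: list[str] = []
                if n_subjects >= 3:
                    cell, notes = _gated_posthoc(wide.to_numpy(),
                                                 PROTOCOLS, alpha)
                    weight_stats[f"{muscle}/{syn}"] = cell
                row["posthoc"] = "; ".join(notes)
                table_rows.append(row)
        files["weights_table"] = out / "weights_table.csv"
        pd.DataFrame(table_rows).to_csv(files["weights_table"], index=False)
        stats_report["weights"] = weight_stats

        if "features" in stages:
            features = pd.DataFrame(feature_rows)
            files["features"] = out / "features.csv"
            features.to_csv(files["features"], index=False)
            files["features_table"] = out / "features_table.csv"
            timing.summarize_features(features).to_csv(
                files["features_table"], index=False)

    if "jumps" in stages:
        jumps = jumps_frame(dataset)
        files["jumps"] = out / "jumps.csv"
        write_jumps_csv(files["jumps"], jumps)

        jumps["height_cm"] = jumpstats.jump_height(
            jumps["flight_time_s"].to_numpy())
        best = (jumps.groupby(["subject", "protocol", "time_point_min"])
                ["height_cm"].max().reset_index())
        # subjects x protocol x time array
        arr = (best.pivot_table(index="subject", columns=[
            "protocol", "time_point_min"], values="height_cm")
            .loc[:, [(p, t) for p in PROTOCOLS for t in TIME_POINTS_MIN]]
            .to_numpy().reshape(-1, len(PROTOCOLS), len(TIME_POINTS_MIN)))

        cells = {f"{p}@{t}": arr[:, pi, ti]
                 for pi, p in enumerate(PROTOCOLS)
                 for ti, t in enumerate(TIME_POINTS_MIN)}
        gate = jumpstats.shapiro_gate(cells, alpha=alpha)
        jump_stats: dict = {"parametric": gate.parametric,
                            "shapiro_p": gate.p_values}
        table_rows = []
        if gate.parametric:
            two_way = jumpstats.two_way_rm_anova(arr, ("protocol", "time"))
            jump_stats["two_way"] = [dataclasses.asdict(r) for r in two_way]
            gate_sig = any(r.p < alpha for r in two_way
                           if "protocol" in r.effect_name)
        else:
            two_way = None
            gate_sig = True   # non-parametric branch gates per time point
        jump_stats["per_time_point"] = {}
        for ti, minutes in enumerate(TIME_POINTS_MIN):
            values = arr[:, :, ti]
            means = {p: float(values[:, pi].mean())
                     for pi, p in enumerate(PROTOCOLS)}
            row = {"time_point_min": minutes}
            for pi, p in enumerate(PROTOCOLS):
                row[f"{p}_mean"] = values[:, pi].mean()
                row[f"{p}_sd"] = values[:, pi].std(ddof=1)
            notes: list[str] = []
            if gate.parametric:
                omnibus = jumpstats.one_way_rm_anova(values)
                cell: dict = {"omnibus": dataclasses.asdict(omnibus)}
                row["F"] = omnibus.F
                row["p"] = omnibus.p
                if gate_sig and omnibus.p < alpha:
                    posthoc = jumpstats.posthoc_pairwise(
                        values, labels=PROTOCOLS, parametric=True)
                    cell["posthoc"] = [_stat_to_dict(r) for r in posthoc]
                    notes = _annotate(posthoc, means, alpha)
            else:
                omnibus = jumpstats.friedman_test(values, labels=PROTOCOLS)
                cell = {"omnibus": _stat_to_dict(omnibus)}
                row["chi2"] = omnibus.statistic
                row["p"] = omnibus.p_raw
                if not omnibus.degenerate and omnibus.p_raw < alpha:
                    posthoc = jumpstats.posthoc_pairwise(
                        values, labels=PROTOCOLS, parametric=False)
                    cell["posthoc"] = [_stat_to_dict(r) for r in posthoc]
                    notes = _annotate(posthoc, means, alpha)
            cell["annotations"] = notes
            row["posthoc"] = "; ".join(notes)
            jump_stats["per_time_point"][str(minutes)] = cell
            table_rows.append(row)
        files["jump_table"] = out / "jump_table.csv"
        pd.DataFrame(table_rows).to_csv(files["jump_table"], index=False)
        stats_report["jumps"] = jump_stats

    files["stats"] = out / "stats.json"
    files["stats"].write_text(json.dumps(stats_report, indent=1,
                                         default=float))
    files["config"] = out / "config.yaml"
    config.to_yaml(files["config"])

    from . import __version__
    manifest = RunManifest(
        config=config.to_dict(), version=__version__, seed=config.seed,
        file_hashes={name: _sha256(p) for name, p in files.items()},
        selected_orders=selected_orders, modal_order=modal_order,
        started_at=t0, finished_at=time.time())
    (out / "manifest.json").write_text(json.dumps(
        dataclasses.asdict(manifest), indent=1, default=float))
    log.removeHandler(handler)
    handler.close()
    return manifest
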