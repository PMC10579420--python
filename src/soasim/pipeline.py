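"""End-to-end study orchestration with file artifacts.

Stages (each reads the previous stage's CSV/JSON artifacts from the
output directory):

1. ``generate`` — synthetic cohort: behavioral and profile CSVs.
2. ``train`` — per-replicate BPTT training, reproduction checks, one
   weight JSON per model subject plus a cohort manifest CSV.
3. ``lesion`` — the configured lesion suite over all passing model
   subjects; one long-format yes-rate CSV per lesion kind.
4. ``report`` — distribution distances against the synthetic
   schizophrenia-pattern reference, classification counts, group mean
   curves and the context-unit correlation summary, as one JSON.

Every artifact directory carries ``manifest.json`` with the config hash
and master seed, and a rerun from the same config is byte-identical.
"""
from __future__ import annotations

import dataclasses
import datetime
import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import behavior, evaluation, lesions, training
from .behavior import BehavioralDataset, SubjectProfile, Trial
from .constants import ACTION_LINKED, EPA, EPA_OFFSETS_MS
from .encoding import EncodingConfig, build_test_set
from .errors import ConfigurationError
from .evaluation import (
    classify_m_subject,
    distribution_distance,
    group_curves,
    rate_distribution,
    unit_correlation_report,
    window_summary,
)
from .lesions import HEALTHY, LesionConfig, model_curve, run_lesion_experiment
from .rnn import RNNParams, run_batch
from .encoding import stack_inputs
from .training import MSubject, TrainingConfig, make_m_subjects, reproduction_check

DEFAULT_LESION_SUITE = (
    LesionConfig(kind="td_context"),
    LesionConfig(kind="noise", noise_level=0.01),
    LesionConfig(kind="td_output"),
    LesionConfig(kind="td_input"),
    LesionConfig(kind="reduced_gain", gain_value=0.99),
)


@dataclass(frozen=True)
class RunConfig:
    master_seed: int = 0
    n_subjects: int = 17
    n_replicates: int = 10
    n_test_per_condition: int = 100
    reproduction_threshold: float = 0.25
    encoding: EncodingConfig = field(default_factory=EncodingConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    lesion_suite: tuple[LesionConfig, ...] = DEFAULT_LESION_SUITE
    n_bins: int = 11
    class_thresholds: tuple[float, float] = (-2.0, 2.0)
    rate_scale: float = 10.0

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self) -> str:
        return yaml.safe_dump(json.loads(json.dumps(self.to_dict())), sort_keys=True)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "encoding" in d:
            d["encoding"] = EncodingConfig(**d["encoding"])
        if "training" in d:
            t = dict(d["training"])
            if "loss_weights" in t:
                t["loss_weights"] = tuple(t["loss_weights"])
            d["training"] = TrainingConfig(**t)
        if "lesion_suite" in d:
            d["lesion_suite"] = tuple(LesionConfig(**l) for l in d["lesion_suite"])
        if "class_thresholds" in d:
            d["class_thresholds"] = tuple(d["class_thresholds"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(text) or {})

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def smoke_config(master_seed: int = 0) -> RunConfig:
    """Small profile: 3 subjects x 2 replicates, 20 test trials/condition."""
    return RunConfig(
        master_seed=master_seed,
        n_subjects=3,
        n_replicates=2,
        n_test_per_condition=20,
    )


def _to_csv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, index=False)


def _read_csv(path: Path) -> pd.DataFrame:
    # the default float parser is fast but lossy; round_trip restores
    # the exact written doubles
    return pd.read_csv(path, float_precision="round_trip")


def _log(out: Path, message: str) -> None:
    stamp = datetime.datetime.now().isoformat(timespec="seconds")
    with (out / "run.log").open("a") as fh:
        fh.write(f"{stamp} {message}\n")


def _write_manifest(out: Path, cfg: RunConfig, stage: str) -> None:
    manifest = {"stage": stage, "config_hash": cfg.config_hash(), "master_seed": cfg.master_seed}
    path = out / "manifest.json"
    merged = json.loads(path.read_text()) if path.exists() else {}
    merged[stage] = manifest
    path.write_text(json.dumps(merged, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# CSV round trips
# ---------------------------------------------------------------------------

def behavioral_frame(datasets: list[BehavioralDataset]) -> pd.DataFrame:
    rows = [
        {
            "subject_id": ds.subject_id,
            "trial_index": i,
            "trial_type": tr.trial_type,
            "condition_ms": tr.condition_ms,
            "rt_ms": tr.rt_ms,
            "response": tr.response,
        }
        for ds in datasets
        for i, tr in enumerate(ds.trials)
    ]
    return pd.DataFrame(rows)


def profile_frame(profiles: list[SubjectProfile]) -> pd.DataFrame:
    rows = []
    for p in profiles:
        row = {
            "subject_id": p.subject_id,
            "inflection_ms": p.inflection_ms,
            "slope": p.slope,
            "upper_asymptote": p.upper_asymptote,
            "lower_asymptote": p.lower_asymptote,
            "rt_mean_ms": p.rt_mean_ms,
            "rt_sd_ms": p.rt_sd_ms,
        }
        for off, prob in zip(EPA_OFFSETS_MS, p.epa_yes_prob):
            row[f"epa_yes_prob_{off}"] = prob
        rows.append(row)
    return pd.DataFrame(rows)


def read_profiles(path: Path) -> list[SubjectProfile]:
    df = _read_csv(path)
    return [
        SubjectProfile(
            subject_id=str(r["subject_id"]),
            inflection_ms=float(r["inflection_ms"]),
            slope=float(r["slope"]),
            upper_asymptote=float(r["upper_asymptote"]),
            lower_asymptote=float(r["lower_asymptote"]),
            epa_yes_prob=tuple(float(r[f"epa_yes_prob_{off}"]) for off in EPA_OFFSETS_MS),
            rt_mean_ms=float(r["rt_mean_ms"]),
            rt_sd_ms=float(r["rt_sd_ms"]),
        )
        for _, r in df.iterrows()
    ]


def read_behavior(path: Path, profiles: dict[str, SubjectProfile]) -> list[BehavioralDataset]:
    df = _read_csv(path)
    out = []
    for sid, grp in df.groupby("subject_id", sort=False):
        grp = grp.sort_values("trial_index")
        trials = tuple(
            Trial(
                trial_type=str(r.trial_type),
                condition_ms=int(r.condition_ms),
                rt_ms=float(r.rt_ms),
                response=int(r.response),
            )
            for r in grp.itertuples()
        )
        out.append(BehavioralDataset(subject_id=str(sid), trials=trials, profile=profiles[str(sid)]))
    return out


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def cmd_generate(cfg: RunConfig, out: str | Path) -> list[BehavioralDataset]:
    out = Path(out)
    out.mkdir(parents=True, exist_ok=True)
    cohort = behavior.generate_cohort(cfg.n_subjects, cfg.master_seed)
    _to_csv(behavioral_frame(cohort), out / "behavior.csv")
    _to_csv(profile_frame([ds.profile for ds in cohort]), out / "profiles.csv")
    _write_manifest(out, cfg, "generate")
    _log(out, f"generate: seed={cfg.master_seed} subjects={len(cohort)}")
    return cohort


def _test_set_seed(cfg: RunConfig, subject_index: int, replicate: int) -> np.random.SeedSequence:
    return np.random.SeedSequence([cfg.master_seed, subject_index, 2, replicate])


def load_cohort(out: Path) -> list[BehavioralDataset]:
    profiles = {p.subject_id: p for p in read_profiles(out / "profiles.csv")}
    return read_behavior(out / "behavior.csv", profiles)


def cmd_train(cfg: RunConfig, out: str | Path) -> list[MSubject]:
    out = Path(out)
    for name in ("behavior.csv", "profiles.csv"):
        if not (out / name).exists():
            raise ConfigurationError(f"missing input {out / name}; run the generate stage first")
    cohort = load_cohort(out)
    model_dir = out / "models"
    model_dir.mkdir(exist_ok=True)
    m_subjects: list[MSubject] = []
    rows = []
    for si, ds in enumerate(cohort):
        reps = make_m_subjects(
            ds, cfg.n_replicates, replace(cfg.training, seed=cfg.master_seed), cfg.encoding
        )
        for m in reps:
            test = build_test_set(
                ds.profile, cfg.n_test_per_condition, _test_set_seed(cfg, si, m.replicate_index),
                cfg.encoding,
            )
            reproduction_check(m, test, ds, cfg.reproduction_threshold, cfg.encoding)
            m.params.save(model_dir / f"{m.m_subject_id}.json")
            rows.append(
                {
                    "m_subject_id": m.m_subject_id,
                    "source_subject_id": m.source_subject_id,
                    "replicate": m.replicate_index,
                    "training_error": m.training_error,
                    "generalization_error": m.generalization_error,
                    "reproduction_pass": m.reproduction_pass,
                }
            )
            m_subjects.append(m)
    _to_csv(pd.DataFrame(rows), out / "m_subjects.csv")
    _write_manifest(out, cfg, "train")
    n_pass = sum(r["reproduction_pass"] for r in rows)
    excluded = [r["m_subject_id"] for r in rows if not r["reproduction_pass"]]
    _log(out, f"train: seed={cfg.master_seed} models={len(rows)} pass={n_pass} excluded={excluded}")
    return m_subjects


def load_m_subjects(out: Path, passing_only: bool = False) -> list[MSubject]:
    df = pd.read_csv(out / "m_subjects.csv")
    ms = []
    for r in df.itertuples():
        if passing_only and not bool(r.reproduction_pass):
            continue
        ms.append(
            MSubject(
                m_subject_id=str(r.m_subject_id),
                params=RNNParams.load(out / "models" / f"{r.m_subject_id}.json"),
                source_subject_id=str(r.source_subject_id),
                replicate_index=int(r.replicate),
                training_error=float(r.training_error),
                generalization_error=float(r.generalization_error),
                reproduction_pass=bool(r.reproduction_pass),
            )
        )
    return ms


def _rebuild_test_sets(cfg: RunConfig, out: Path, m_subjects: list[MSubject]):
    cohort = load_cohort(out)
    index = {ds.subject_id: (si, ds) for si, ds in enumerate(cohort)}
    test_sets = {}
    for m in m_subjects:
        si, ds = index[m.source_subject_id]
        test_sets[m.m_subject_id] = build_test_set(
            ds.profile, cfg.n_test_per_condition, _test_set_seed(cfg, si, m.replicate_index),
            cfg.encoding,
        )
    return test_sets


def _curve_rows(result: lesions.LesionRunResult) -> list[dict]:
    rows = []
    for tt, rates_l, rates_h in (
        (ACTION_LINKED, result.yes_rate_curve.action_rates, result.healthy_curve.action_rates),
        (EPA, result.yes_rate_curve.epa_rates, result.healthy_curve.epa_rates),
    ):
        for ms in rates_l:
            rows.append(
                {
                    "m_subject_id": result.m_subject_id,
                    "lesion_kind": result.lesion.kind,
                    "trial_type": tt,
                    "condition_ms": ms,
                    "yes_rate_lesioned": rates_l[ms],
                    "yes_rate_healthy": rates_h[ms],
                }
            )
    return rows


def cmd_lesion(cfg: RunConfig, out: str | Path) -> dict[str, list[lesions.LesionRunResult]]:
    out = Path(out)
    if not (out / "m_subjects.csv").exists():
        raise ConfigurationError(f"missing {out / 'm_subjects.csv'}; run the train stage first")
    m_subjects = load_m_subjects(out, passing_only=True)
    if not m_subjects:
        for lesion in cfg.lesion_suite:
            pd.DataFrame(
                columns=[
                    "m_subject_id", "lesion_kind", "trial_type", "condition_ms",
                    "yes_rate_lesioned", "yes_rate_healthy",
                ]
            ).to_csv(out / f"lesion_{lesion.kind}.csv", index=False)
        _write_manifest(out, cfg, "lesion")
        return {}
    test_sets = _rebuild_test_sets(cfg, out, m_subjects)
    healthy = {
        m.m_subject_id: model_curve(m.params, test_sets[m.m_subject_id], HEALTHY)
        for m in m_subjects
    }
    all_results = {}
    for lesion in cfg.lesion_suite:
        lesion = replace(lesion, seed=lesion.seed or cfg.master_seed)
        results = run_lesion_experiment(m_subjects, test_sets, lesion, healthy)
        _to_csv(
            pd.DataFrame([row for res in results for row in _curve_rows(res)]),
            out / f"lesion_{lesion.kind}.csv",
        )
        all_results[lesion.kind] = results
        _log(out, f"lesion {lesion.kind}: seed={lesion.seed} models={len(results)}")
    _write_manifest(out, cfg, "lesion")
    return all_results


def _distribution_pair(curves: list[evaluation.YesRateCurve], n_bins: int):
    summaries = [window_summary(c) for c in curves]
    return (
        rate_distribution([s.short_avg for s in summaries], n_bins),
        rate_distribution([s.long_avg for s in summaries], n_bins),
    )


def unit_correlation_inputs(
    m_subjects: list[MSubject], test_sets
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Pre-jump context activations, judgments and latencies per subject
    over action-linked test trials (unlesioned runs)."""
    per_subject = {}
    for m in m_subjects:
        seqs = [s for s in test_sets[m.m_subject_id] if s.trial_type == ACTION_LINKED]
        res = run_batch(m.params, stack_inputs(seqs))
        jump = np.array([s.event_times["jump"] for s in seqs])
        # c at the step immediately before the jump
        act = res.c[np.arange(len(seqs)), jump - 1]
        per_subject[m.m_subject_id] = (
            act,
            res.final_soa > evaluation.YES_THRESHOLD,
            np.array([s.condition_ms for s in seqs], dtype=float),
        )
    return per_subject


def cmd_report(cfg: RunConfig, out: str | Path, plots: bool = False) -> dict:
    out = Path(out)
    lesion_kinds = [l.kind for l in cfg.lesion_suite]
    for kind in lesion_kinds:
        if not (out / f"lesion_{kind}.csv").exists():
            raise ConfigurationError(
                f"missing {out / f'lesion_{kind}.csv'}; run the lesion stage first"
            )
    m_subjects = load_m_subjects(out, passing_only=True)
    test_sets = _rebuild_test_sets(cfg, out, m_subjects)

    sz_curves = behavior.generate_sz_reference("mixed", seed=cfg.master_seed)
    ref_short, ref_long = _distribution_pair(sz_curves, cfg.n_bins)

    report: dict = {
        "config_hash": cfg.config_hash(),
        "n_m_subjects": len(m_subjects),
        "lesions": {},
    }
    curves_by_kind: dict[str, dict] = {}
    for kind in lesion_kinds:
        df = pd.read_csv(out / f"lesion_{kind}.csv")
        lcurves, hcurves = {}, {}
        for sid, grp in df.groupby("m_subject_id", sort=False):
            def _curve(col):
                act = {int(r.condition_ms): float(getattr(r, col))
                       for r in grp.itertuples() if r.trial_type == ACTION_LINKED}
                epa = {int(r.condition_ms): float(getattr(r, col))
                       for r in grp.itertuples() if r.trial_type == EPA}
                return evaluation.YesRateCurve(act, epa)
            lcurves[sid] = _curve("yes_rate_lesioned")
            hcurves[sid] = _curve("yes_rate_healthy")
        curves_by_kind[kind] = {"lesioned": lcurves, "healthy": hcurves}
        if not lcurves:
            report["lesions"][kind] = {"n": 0}
            continue
        mod_short, mod_long = _distribution_pair(list(lcurves.values()), cfg.n_bins)
        dist = distribution_distance(ref_short, ref_long, mod_short, mod_long)
        cls = [
            classify_m_subject(
                lcurves[sid], hcurves[sid], sid, cfg.class_thresholds, cfg.rate_scale
            )
            for sid in lcurves
        ]
        counts = {lab: sum(c.label == lab for c in cls)
                  for lab in ("excessive", "diminished", "sz_pattern", "no_change")}
        groups = group_curves([(c, lcurves[c.m_subject_id]) for c in cls])
        summaries = [window_summary(c) for c in lcurves.values()]
        report["lesions"][kind] = {
            "n": len(lcurves),
            "mse_vs_reference": dist["mse"],
            "kl_vs_reference": dist["kl"],
            "classification_counts": counts,
            "mean_short_window": float(np.mean([s.short_avg for s in summaries])),
            "mean_long_window": float(np.mean([s.long_avg for s in summaries])),
            "group_mean_curves": {
                lab: {"mean": g["mean"].tolist(), "se": g["se"].tolist(), "n": int(g["n"])}
                for lab, g in groups.items()
            },
        }

    if m_subjects:
        rep = unit_correlation_report(unit_correlation_inputs(m_subjects, test_sets))
        report["unit_correlation"] = {
            "mean_soa_units": rep.mean_soa_units,
            "mean_latency_units": rep.mean_latency_units,
            "n_skipped": len(rep.skipped),
        }

    (out / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    if plots:
        _plot_report(out, cfg, curves_by_kind)
    _write_manifest(out, cfg, "report")
    _log(out, f"report: lesions={list(report['lesions'])}")
    return report


def _plot_report(out: Path, cfg: RunConfig, curves_by_kind: dict) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .constants import ACTION_LATENCIES_MS

    for kind, curves in curves_by_kind.items():
        if not curves["lesioned"]:
            continue
        fig, ax = plt.subplots(figsize=(5, 3.5))
        arr_l = np.stack([c.as_array()[:11] for c in curves["lesioned"].values()])
        arr_h = np.stack([c.as_array()[:11] for c in curves["healthy"].values()])
        ax.plot(ACTION_LATENCIES_MS, arr_h.mean(axis=0), "k-o", label="healthy", ms=3)
        ax.plot(ACTION_LATENCIES_MS, arr_l.mean(axis=0), "r-o", label=kind, ms=3)
        ax.set_xlabel("jumping latency (ms)")
        ax.set_ylabel("yes rate")
        ax.set_ylim(-0.05, 1.05)
        ax.legend(frameon=False)
        fig.tight_layout()
        fig.savefig(out / f"curve_{kind}.png", dpi=120)
        plt.close(fig)


def cmd_all(cfg: RunConfig, out: str | Path, plots: bool = False) -> dict:
    cmd_generate(cfg, out)
    cmd_train(cfg, out)
    cmd_lesion(cfg, out)
    return cmd_report(cfg, out, plots)
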