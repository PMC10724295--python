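"""Config-driven end-to-end runs: simulate → preprocess → RDM → RSA / vMMN.

A single master seed fans out to per-stage seeds through a NumPy
``SeedSequence`` (spawn order: character table, cohort, RSA permutations,
vMMN permutations, behaviour), so a run is fully reproducible from its
config, and the resolved config is written verbatim next to the results.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import behavior as _behavior
from .design import INCONSISTENT_CATEGORIES, make_default_character_table
from .preprocess import preprocess_recording, retained_counts
from .rdm import DEFAULT_TIMES_MS, model_rdms, neural_rdm_timecourse
from .rsa import (
    ClusterResult,
    condition_difference,
    default_controls,
    rsa_timecourse,
    sign_permutation_cluster_test,
)
from .simulate import default_effects, iter_cohort
from .vmmn import cluster_mass_permutation_test, differential_waveform


class ConfigError(ValueError):
    pass


@dataclass
class PipelineConfig:
    """Resolved parameters for an end-to-end run.

    Defaults reproduce the full study conditions (45 subjects, 420-trial
    oddball blocks, 480-trial equal-probability block, 10,000 permutations);
    :func:`demo_config` returns a desk-scale variant.
    """

    # design
    n_trials_oddball: int = 420
    n_trials_equal: int = 480
    p_deviant: float = 0.25
    p_target: float = 0.1
    # simulation
    n_subjects: int = 45
    consistency_amplitude: float = 6.0
    frequency_amplitude: float = 6.0
    vmmn_amplitude: float = 2.0
    between_subject_sd: float = 1.5
    noise_sd: float = 8.0
    pink_fraction: float = 0.5
    # preprocessing
    band: tuple[float, float] = (0.1, 40.0)
    baseline_ms: tuple[float, float] = (-300.0, -200.0)
    rejection_threshold_uv: float = 100.0
    # analysis
    n_perm: int = 10000
    cluster_alpha: float = 0.05
    vmmn_cluster_threshold_p: float = 0.025
    corrected_alpha: float = 0.05
    use_rating_models: bool = False
    # reproducibility
    seed: int = 0

    def validate(self) -> None:
        checks = [
            ("n_trials_oddball", self.n_trials_oddball >= 12),
            ("n_trials_equal", self.n_trials_equal % 12 == 0),
            ("p_deviant", 0 <= self.p_deviant <= 0.5),
            ("p_target", 0 <= self.p_target < 0.5),
            ("n_subjects", self.n_subjects >= 2),
            ("noise_sd", self.noise_sd >= 0),
            ("pink_fraction", 0 <= self.pink_fraction <= 1),
            ("band", 0 < self.band[0] < self.band[1]),
            ("rejection_threshold_uv", self.rejection_threshold_uv > 0),
            ("n_perm", self.n_perm >= 1),
            ("cluster_alpha", 0 < self.cluster_alpha < 1),
            ("corrected_alpha", 0 < self.corrected_alpha < 1),
        ]
        bad = [name for name, ok in checks if not ok]
        if bad:
            raise ConfigError(f"invalid config fields: {bad}")

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        raw = json.loads(text)
        names = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - names
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**{k: tuple(v) if isinstance(v, list) else v for k, v in raw.items()})
        cfg.validate()
        return cfg


def demo_config(seed: int = 0) -> PipelineConfig:
    """Desk-scale configuration for quick end-to-end runs."""
    return PipelineConfig(
        n_trials_oddball=120,
        n_trials_equal=120,
        n_subjects=8,
        n_perm=500,
        seed=seed,
    )


def _stage_seeds(master: int) -> dict[str, int]:
    ss = np.random.SeedSequence(master)
    kids = ss.spawn(5)
    names = ("table", "cohort", "rsa_perm", "vmmn_perm", "behavior")
    return {
        name: int(kid.generate_state(1)[0] % (2**31 - 1))
        for name, kid in zip(names, kids)
    }


def _cluster_result_dict(res: ClusterResult) -> dict:
    return {
        "statistic": res.statistic,
        "n_perm": res.n_perm,
        "corrected_alpha": res.corrected_alpha,
        "clusters": [
            {
                "window_ms": list(c.window_ms),
                "stat": c.stat,
                "p_value": c.p_value,
                "significant": c.significant,
                "effect_size": c.effect_size,
            }
            for c in res.clusters
        ],
    }


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> dict:
    """Execute the full analysis and return (and optionally write) results.

    Returns a dict with keys ``rsa`` (cluster tests per model and condition,
    including the oddball-minus-equal difference and the radical-control
    screen), ``vmmn`` (cluster-mass tests per category and ROI, sign
    convention deviant minus equiprobable), ``behavior`` (hit/false-alarm
    summaries per block type) and ``retained`` (epoch-rejection log).
    """
    config.validate()
    seeds = _stage_seeds(config.seed)
    table = make_default_character_table(seeds["table"])
    effects = default_effects(
        consistency_amplitude=config.consistency_amplitude,
        frequency_amplitude=config.frequency_amplitude,
        vmmn_amplitude=config.vmmn_amplitude,
    )
    cohort = iter_cohort(
        n_subjects=config.n_subjects,
        table=table,
        effects=effects,
        between_subject_sd=config.between_subject_sd,
        n_trials_oddball=config.n_trials_oddball,
        n_trials_equal=config.n_trials_equal,
        p_deviant=config.p_deviant,
        p_target=config.p_target,
        noise_sd=config.noise_sd,
        pink_fraction=config.pink_fraction,
        seed=seeds["cohort"],
    )

    models = model_rdms(table, ratings=config.use_rating_models)
    model_names = ("orthographic", "phonological", "semantic", "frequency",
                   "radical_control")
    times = DEFAULT_TIMES_MS

    tc = {  # model -> condition -> list over subjects of rho arrays
        m: {"oddball": [], "equal_probability": [], "difference": []}
        for m in model_names
    }
    # per-category contrasts plus the pooled all-deviant contrast (None)
    diff_waves: dict[tuple[str | None, str], list[np.ndarray]] = {
        (cat, roi): []
        for cat in (*INCONSISTENT_CATEGORIES, None)
        for roi in ("left", "right")
    }
    retained_logs = []
    wave_times = None
    session_sequences = []  # (subject_id, sequences) for behavioural scoring

    # recordings are simulated lazily and analysed one at a time: a cohort of
    # continuous study-scale recordings would not fit in memory at once
    for sub in cohort:
        session_sequences.append(sub.sequences)
        ep = preprocess_recording(
            sub.recording,
            low=config.band[0],
            high=config.band[1],
            baseline_ms=config.baseline_ms,
            threshold=config.rejection_threshold_uv,
        )
        retained_logs.append(retained_counts(ep).assign(subject=sub.subject_id))
        stacks = {
            cond: neural_rdm_timecourse(ep, cond, table, times_ms=times)
            for cond in ("oddball", "equal_probability")
        }
        for m in model_names:
            ctrl_names = default_controls(m)
            ctrls = [models[c] for c in ctrl_names]
            per_cond = {}
            for cond in ("oddball", "equal_probability"):
                t = rsa_timecourse(
                    stacks[cond], models[m], ctrls,
                    model_name=m, control_names=ctrl_names,
                )
                per_cond[cond] = t
                tc[m][cond].append(t.partial_rho)
            d = condition_difference(per_cond["oddball"], per_cond["equal_probability"])
            tc[m]["difference"].append(d.partial_rho)
        for (cat, roi), store in diff_waves.items():
            w = differential_waveform(ep, cat, roi)
            store.append(w.values)
            wave_times = w.times_ms

    rsa_rng = np.random.default_rng(seeds["rsa_perm"])
    rsa_results = {}
    for m in model_names:
        rsa_results[m] = {}
        for cond in ("oddball", "equal_probability", "difference"):
            X = np.vstack(tc[m][cond])
            res = sign_permutation_cluster_test(
                X, times_ms=times, n_perm=config.n_perm,
                cluster_alpha=config.cluster_alpha,
                corrected_alpha=config.corrected_alpha,
                seed=int(rsa_rng.integers(0, 2**31 - 1)),
            )
            rsa_results[m][cond] = _cluster_result_dict(res)
            rsa_results[m][cond]["group_mean_rho"] = X.mean(axis=0).tolist()

    vmmn_rng = np.random.default_rng(seeds["vmmn_perm"])
    vmmn_results = {"sign_convention": "deviant_minus_equiprobable"}
    for (cat, roi), waves in diff_waves.items():
        X = np.vstack(waves)
        res = cluster_mass_permutation_test(
            X, times_ms=wave_times, n_perm=config.n_perm,
            cluster_threshold_p=config.vmmn_cluster_threshold_p,
            corrected_alpha=config.corrected_alpha,
            seed=int(vmmn_rng.integers(0, 2**31 - 1)),
        )
        vmmn_results[f"{cat or 'all'}_{roi}"] = _cluster_result_dict(res)

    beh_rng = np.random.default_rng(seeds["behavior"])
    beh: dict[str, list[dict]] = {}
    for seqs in session_sequences:
        for seq in seqs:
            if not any(t.is_target for t in seq.trials):
                continue  # target-free designs have nothing to score
            log = _behavior.simulate_response_log(
                seq, seed=int(beh_rng.integers(0, 2**31 - 1))
            )
            beh.setdefault(seq.block, []).append(_behavior.score_responses(log))
    behavior_results = {
        block: {
            "mean_hit_rate": float(np.mean([s["hit_rate"] for s in scores])),
            "mean_false_alarm_rate": float(
                np.mean([s["false_alarm_rate"] for s in scores])
            ),
            "mean_latency_ms": float(
                np.nanmean([s["mean_latency_ms"] for s in scores])
            ),
        }
        for block, scores in beh.items()
    }

    results = {
        "seeds": seeds,
        "rsa": rsa_results,
        "vmmn": vmmn_results,
        "behavior": behavior_results,
    }

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.json").write_text(config.to_json())
        (out / "results.json").write_text(json.dumps(results, indent=2, sort_keys=True))
        pd.concat(retained_logs, ignore_index=True).to_csv(
            out / "retained_counts.tsv", sep="\t", index=False
        )
        rows = []
        for m in model_names:
            for cond in ("oddball", "equal_probability", "difference"):
                for rho_t, t in zip(
                    np.vstack(tc[m][cond]).mean(axis=0), times
                ):
                    rows.append(
                        {"model": m, "condition": cond, "time_ms": t,
                         "group_mean_partial_rho": rho_t}
                    )
        pd.DataFrame(rows).to_csv(out / "rsa_timecourses.tsv", sep="\t", index=False)
    return results
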