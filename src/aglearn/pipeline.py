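"""End-to-end pipeline: stimuli -> model predictions -> simulation -> analysis.

Every stage is deterministic given the top-level seed; per-stage seeds are
spawned from it so changing one stage's inputs does not perturb another's
randomness. A manifest (``manifest.json``) records the seed, a hash of the
configuration and every file written.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from aglearn import bayes, behavior, stats, stimuli

log = logging.getLogger("aglearn.pipeline")

#: behaviour item classes keyed by the model's item-class labels
_CLASS_TO_BEHAVIOR = {
    "grammatical": "grammatical",
    "single_violation_rep": "rep_violation",
    "single_violation_di": "di_violation",
    "double_violation": "double_violation",
}


@dataclass
class PipelineConfig:
    seed: int = 0
    out_dir: str | Path = "aglearn_output"
    orders: tuple[str, ...] = stimuli.ORDERS
    violation_modes: tuple[str, ...] = stimuli.VIOLATION_MODES
    bayes: bayes.BayesConfig = field(default_factory=bayes.BayesConfig)
    response: behavior.ResponseModelSpec = field(
        default_factory=behavior.ResponseModelSpec
    )
    design: behavior.ExperimentDesign = field(
        default_factory=behavior.ExperimentDesign
    )
    synthesis: stimuli.SynthesisSpec = field(default_factory=stimuli.SynthesisSpec)
    write_pho: bool = True

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["out_dir"] = str(self.out_dir)
        return d

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _stage_seeds(seed: int) -> dict[str, int]:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(2)
    # keep derived seeds in int32 range
    return {
        "stimuli": int(children[0].generate_state(1)[0] % (2**31)),
        "behavior": int(children[1].generate_state(1)[0] % (2**31)),
    }


def run_pipeline(config: PipelineConfig | None = None) -> dict:
    """Run all stages and return the manifest (also written to disk)."""
    config = config or PipelineConfig()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    manifest: dict = {
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "config": config.to_dict(),
        "stage_seeds": seeds,
        "files": [],
        "stages": {},
    }

    def _record(path: Path, kind: str) -> None:
        manifest["files"].append({"path": str(path.relative_to(out)), "kind": kind})

    try:
        # ---- stage 1: stimuli -------------------------------------------
        t0 = time.perf_counter()
        stim_dir = out / "stimuli"
        stim_dir.mkdir(exist_ok=True)
        pho_dir = out / "pho"
        if config.write_pho:
            pho_dir.mkdir(exist_ok=True)
        n_sets = 0
        for i, order in enumerate(config.orders):
            grammar = stimuli.GrammarSpec(order)
            fam = stimuli.generate_familiarization(
                grammar, n=36, seed=seeds["stimuli"] + i
            )
            for j, mode in enumerate(config.violation_modes):
                test = stimuli.generate_test_set(
                    grammar, mode, seed=seeds["stimuli"] + 10 * (i + 1) + j
                )
                combined = stimuli.StimulusSet(
                    items=list(fam.items) + list(test.items), role="combined"
                )
                path = stim_dir / f"{order}_{mode}.csv"
                stimuli.write_stimulus_csv(combined, path)
                _record(path, "stimulus_set")
                n_sets += 1
                if config.write_pho:
                    for item in combined:
                        p = pho_dir / f"{item.item_id}.pho"
                        p.write_text(stimuli.render_pho(item, config.synthesis))
                        _record(p, "pho")
        manifest["stages"]["stimuli"] = {
            "n_stimulus_sets": n_sets,
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("stimuli stage done (%d sets)", n_sets)

        # ---- stage 2: model predictions ---------------------------------
        t0 = time.perf_counter()
        pred_dir = out / "predictions"
        pred_dir.mkdir(exist_ok=True)
        for name, cfg in (
            ("full_model", config.bayes),
            (
                "no_conjunction",
                dataclasses.replace(config.bayes, include_conjunction=False),
            ),
        ):
            pred = bayes.predict_all(cfg)
            path = pred_dir / f"{name}.json"
            path.write_text(
                json.dumps(bayes.predictions_as_dict(pred), indent=2) + "\n"
            )
            _record(path, "predictions")
        manifest["stages"]["predict"] = {
            "seconds": round(time.perf_counter() - t0, 3)
        }
        log.info("prediction stage done")

        # ---- stage 3: behavioural simulation ----------------------------
        t0 = time.perf_counter()
        trials = behavior.simulate_trials(
            config.response, config.design, seed=seeds["behavior"]
        )
        trials_path = out / "trials.csv"
        trials.to_csv(trials_path, index=False)
        _record(trials_path, "trial_table")
        sidecar = out / "trials_config.json"
        sidecar.write_text(
            json.dumps(
                {
                    "seed": seeds["behavior"],
                    "response_model": dataclasses.asdict(config.response),
                    "design": dataclasses.asdict(config.design),
                },
                indent=2,
            )
            + "\n"
        )
        _record(sidecar, "trial_table_config")
        manifest["stages"]["simulate"] = {
            "n_trials": int(len(trials)),
            "seconds": round(time.perf_counter() - t0, 3),
        }
        log.info("simulation stage done (%d trials)", len(trials))

        # ---- stage 4: analyses ------------------------------------------
        t0 = time.perf_counter()
        analysis = analyze_trials(trials)
        ana_dir = out / "analysis"
        ana_dir.mkdir(exist_ok=True)
        path = ana_dir / "analysis.json"
        path.write_text(json.dumps(analysis, indent=2, default=float) + "\n")
        _record(path, "analysis_bundle")
        manifest["stages"]["analyze"] = {
            "seconds": round(time.perf_counter() - t0, 3)
        }
        log.info("analysis stage done")
    except Exception as exc:
        manifest["error"] = {"stage": _current_stage(manifest), "message": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
        raise

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest


def _current_stage(manifest: dict) -> str:
    done = set(manifest["stages"])
    for stage in ("stimuli", "predict", "simulate", "analyze"):
        if stage not in done:
            return stage
    return "finalize"


def analyze_trials(trials) -> dict:
    """Run the analysis battery on a trial table; JSON-serializable output."""
    rates = behavior.summarize_rates(trials)
    per_participant = behavior.participant_means(trials)
    chance_table = stats.rates_vs_chance_table(per_participant)

    # 2x2 mixed ANOVA on single violations: regularity (within) x order
    singles = per_participant[
        per_participant["item_class"].isin(["rep_violation", "di_violation"])
    ].copy()
    singles = (
        singles.groupby(["order", "item_class", "participant_id"], observed=True)[
            "rejected"
        ]
        .mean()
        .reset_index()
        .rename(columns={"item_class": "regularity", "rejected": "rate"})
    )
    anova = stats.mixed_anova_2x2(
        singles, dv="rate", within="regularity", between="order"
    )

    coefs = stats.fit_rejection_logistic(trials)
    return {
        "cell_rates": rates.to_dict(orient="records"),
        "tests_vs_chance": chance_table.to_dict(orient="records"),
        "mixed_anova_single_violations": {
            k: {
                "F": r.statistic,
                "df": list(r.df) if isinstance(r.df, tuple) else r.df,
                "p": r.p_uncorrected,
                "partial_eta_sq": r.effect_size,
            }
            for k, r in anova.items()
        },
        "logistic_coefficients": [dataclasses.asdict(c) for c in coefs],
    }
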