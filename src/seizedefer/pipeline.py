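"""End-to-end orchestration: simulate -> label -> train -> trust -> detect ->
defer -> evaluate -> cv, reproducible from a single seeded configuration.

``run_experiment`` produces the four-way regime comparison (classifier
trained on clear-ictal or full-seizure labels x trust model fitted on either
regime), the SVM-confidence LTF baseline, deferral curves in both modes plus
a random-deferral baseline, and one-sided paired significance tests.  All
randomness flows from ``RunConfig.seed``; result bundles embed the config
hash and seed so two runs of the same config are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import yaml

from .classifier import train_classifier
from .cv import lopo_cv_svmconf, make_folds, nested_cv_ltf
from .deferral import deferral_curve
from .detection import seizure_flags
from .labeling import derive_labels
from .metrics import aggregate_cohort, paired_test, patient_metrics, ranking_agreement
from .simulate import SimConfig, generate_cohort
from .trust import fit_trust_model, subsample_training_set

__all__ = ["RunConfig", "run_experiment", "train_fold_classifiers"]

REGIMES = ("ci", "fs")


@dataclass
class RunConfig:
    """Seeded configuration of a full synthetic experiment."""

    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    n_folds: int = 6
    q_grid: tuple = tuple(i / 100 for i in range(21))
    p_low: float = 5.0
    defer_fractions: tuple = (0.0, 0.05, 0.1, 0.2, 0.4, 0.7, 1.0)
    classifier_regimes: tuple = REGIMES
    trust_regimes: tuple = REGIMES
    svm_kernel: str = "linear"
    cls_train_windows: int = 30  # non-seizure 1-min windows/patient for SVM training
    trust_windows: int = 100
    n_components: int = 20
    run_deferral: bool = True
    run_ltf: bool = True
    n_random_deferral: int = 10
    fold_relax: float = 4.0  # widen fold-balance bounds for small cohorts

    def to_yaml(self) -> str:
        d = asdict(self)
        d["sim"]["seizure_duration_range"] = list(d["sim"]["seizure_duration_range"])
        return yaml.safe_dump(d, sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        d = yaml.safe_load(text)
        sim = d.pop("sim", {})
        if "seizure_duration_range" in sim:
            sim["seizure_duration_range"] = tuple(sim["seizure_duration_range"])
        cfg = cls(sim=SimConfig(**sim))
        for k, v in d.items():
            setattr(cfg, k, tuple(v) if isinstance(v, list) else v)
        return cfg

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]


def train_fold_classifiers(cohort, labels, fold_plan, config: RunConfig, regime: str):
    """Patient-independent predictions: for each test fold, an SVM trained on
    the subsampled segments of the remaining folds predicts the fold's
    patients.  Returns (predictions, distances) keyed by patient id."""
    by_id = {p.patient_id: p for p in cohort}
    predictions, distances = {}, {}
    for t, test_fold in enumerate(fold_plan.folds):
        train_ids = [pid for j, f in enumerate(fold_plan.folds) if j != t for pid in f]
        X, y = subsample_training_set(
            [by_id[i] for i in train_ids],
            labels,
            seed=config.seed + 1000 + t,
            n_windows=config.cls_train_windows,
            exclude_artifacts=True,  # routine training-set artifact rejection
        )
        model = train_classifier(X, y, regime=regime, kernel=config.svm_kernel)
        for pid in test_fold:
            d = model.decision_distance(by_id[pid].segments.features)
            distances[pid] = d
            predictions[pid] = (d > 0).astype(np.int8)
    return predictions, distances


def _metric_vectors(per_patient: dict):
    ids = sorted(per_patient)
    out = {}
    for name in ("ds", "fdr_per_24h", "ppv", "f1"):
        pairs = [(i, getattr(per_patient[i], name)) for i in ids]
        out[name] = {i: v for i, v in pairs}
    return out


def _significance(baseline: dict, ltf: dict) -> dict:
    """One-sided Wilcoxon tests, paired per patient, LTF vs baseline."""
    tests = {}
    for name, better in (
        ("ds", "greater"),
        ("fdr_per_24h", "less"),
        ("ppv", "greater"),
        ("f1", "greater"),
    ):
        ids = [
            i
            for i in sorted(baseline)
            if getattr(baseline[i], name) is not None
            and getattr(ltf[i], name) is not None
        ]
        a = [getattr(ltf[i], name) for i in ids]
        b = [getattr(baseline[i], name) for i in ids]
        tests[name] = {
            "direction": better,
            "p_value": paired_test(a, b, better) if ids else None,
        }
    return tests


def run_experiment(config: RunConfig) -> dict:
    """Run the full synthetic study; returns a JSON-serialisable bundle."""
    cohort = generate_cohort(config.sim)
    by_id = {p.patient_id: p for p in cohort}
    n_seg = {pid: by_id[pid].segments.n_segments for pid in by_id}
    labels = {
        reg: {pid: derive_labels(by_id[pid].events, reg, n_seg[pid]) for pid in by_id}
        for reg in REGIMES
    }
    fold_plan = make_folds(
        cohort, n_folds=config.n_folds, seed=config.seed, relax=config.fold_relax
    )

    results: dict = {
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "folds": fold_plan.folds,
        "regimes": {},
    }

    for cls_reg in config.classifier_regimes:
        predictions, distances = train_fold_classifiers(
            cohort, labels[cls_reg], fold_plan, config, cls_reg
        )
        baseline = {
            pid: patient_metrics(
                seizure_flags(predictions[pid]), by_id[pid].events, by_id[pid].duration_s
            )
            for pid in by_id
        }
        entry: dict = {"baseline": aggregate_cohort(list(baseline.values()))}

        if config.run_ltf:
            entry["ltf"] = {}
            for tr_reg in config.trust_regimes:
                res = nested_cv_ltf(
                    cohort,
                    predictions,
                    labels[tr_reg],
                    q_grid=config.q_grid,
                    fold_plan=fold_plan,
                    seed=config.seed,
                    n_components=config.n_components,
                    trust_regime=tr_reg,
                    subsample_windows=config.trust_windows,
                )
                entry["ltf"][f"trust_{tr_reg}"] = {
                    "chosen_q": res.fold_q,
                    "inner_optima": res.inner_optima,
                    "metrics": aggregate_cohort(list(res.per_patient.values())),
                    "significance": _significance(baseline, res.per_patient),
                }
            conf_res = lopo_cv_svmconf(
                cohort, distances, q_grid=config.q_grid
            )
            entry["ltf"]["svm_confidence"] = {
                "chosen": {pid: list(v) for pid, v in conf_res.chosen.items()},
                "metrics": aggregate_cohort(list(conf_res.per_patient.values())),
                "significance": _significance(baseline, conf_res.per_patient),
            }

        if config.run_deferral:
            # trust model per patient (fitted on all others, FS labels) for
            # trust-based deferral scores; SVM confidences use |d|
            trust_scores = {}
            sub = {
                p.patient_id: subsample_training_set(
                    [p], labels["fs"], seed=config.seed + i, n_windows=config.trust_windows
                )
                for i, p in enumerate(cohort)
            }
            for pid in by_id:
                train = [i for i in by_id if i != pid]
                X = np.concatenate([sub[i][0] for i in train])
                y = np.concatenate([sub[i][1] for i in train])
                model = fit_trust_model(X, y, n_components=config.n_components)
                trust_scores[pid] = model.score_samples(
                    by_id[pid].segments.features, predictions[pid]
                )

            def patients_io(score_map):
                return [
                    {
                        "duration_s": by_id[pid].duration_s,
                        "events": by_id[pid].events,
                        "flags": seizure_flags(predictions[pid]),
                        "scores": score_map[pid],
                    }
                    for pid in sorted(by_id)
                ]

            conf_map = {pid: np.abs(distances[pid]) for pid in by_id}
            ids = sorted(by_id)
            entry["kendall_conf_vs_trust"] = ranking_agreement(
                [conf_map[i] for i in ids], [trust_scores[i] for i in ids]
            )
            entry["deferral"] = {}
            for name, score_map in (("svm_confidence", conf_map), ("trust_fs", trust_scores)):
                curves = {}
                for mode in ("flags_first", "flags_not_first"):
                    cur = deferral_curve(
                        patients_io(score_map),
                        config.defer_fractions,
                        p_low=config.p_low,
                        mode=mode,
                    )
                    curves[mode] = [
                        {k: v for k, v in c.items() if k != "per_patient"} for c in cur
                    ]
                curves["random"] = _random_baseline(
                    patients_io(score_map), config
                )
                entry["deferral"][name] = curves

        results["regimes"][cls_reg] = entry
    return results


def _random_baseline(patients_io, config: RunConfig) -> list[dict]:
    """Monte-Carlo random-deferral curve (mean DS/FDR over draws)."""
    out = []
    for frac in config.defer_fractions:
        ds, fdr = [], []
        for k in range(config.n_random_deferral):
            cur = deferral_curve(
                patients_io, [frac], p_low=config.p_low, mode="random",
                seed=config.seed + 5000 + k,
            )[0]
            m = cur["metrics"]
            if m["ds"]["mean"] is not None:
                ds.append(m["ds"]["mean"])
            fdr.append(m["fdr_per_24h"]["mean"])
        out.append(
            {
                "fraction": float(frac),
                "ds_mean": float(np.mean(ds)) if ds else None,
                "fdr_mean": float(np.mean(fdr)),
            }
        )
    return out


def results_to_json(results: dict) -> str:
    return json.dumps(results, indent=2, sort_keys=True, default=_jsonable)


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "as_dict"):
        return obj.as_dict()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")
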