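"""End-to-end study orchestration.

``run_study`` executes the whole protocol on a synthetic profile or a
directory of record CSVs: preprocess -> segment & label -> features ->
patient split -> hyperparameter tuning -> embedded feature selection ->
training -> patient-wise bootstrap evaluation -> paired subset-vs-all
comparison, writing intermediate tables and a manifest that reproduces every
number.  All randomness flows from the single master seed through named
substreams; a hard leakage audit asserts that no test patient is touched by
any training-side stage.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import io as sio
from .classifiers import (
    ALGORITHMS,
    ModelSpec,
    NoCrossingError,
    fit,
    fit_ml_threshold,
    predict,
    tune,
)
from .evaluation import bootstrap_metrics, metrics, patient_split
from .features import build_dataset, standardize
from .preprocess import label_and_filter, preprocess_record, segment_record
from .records import SH
from .selection import evaluate_subset, one_se_subset, rfe_bootstrap
from .synthetic import PROFILES, gen_corpus

log = logging.getLogger(__name__)

_STAGES = ("corpus", "split", "tune", "selection", "fit", "bootstrap")


class ConfigError(ValueError):
    """Invalid run configuration (raised before any computation)."""


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and partial results."""

    def __init__(self, stage: str, partial: dict, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.partial = partial


@dataclass
class RunConfig:
    """Study configuration; defaults mirror the full protocol, scaled sizes
    are the caller's choice."""

    source: str = "public_like"  # profile name or a directory of record CSVs
    durations: tuple[int, ...] = (4, 8)
    split_fraction: float = 0.8
    algorithms: tuple[str, ...] = ALGORITHMS
    B: int = 500
    selection_method: str | None = "BSTsel"
    selection_B: int = 50
    seed: int = 0
    out_dir: str | None = None
    #: also evaluate every feature alone with the maximum-likelihood
    #: threshold rule (single-feature Se/Sp table)
    single_features: bool = False
    # synthetic-source knobs
    n_patients: int = 30
    records_per_patient: int = 2
    record_duration_s: float = 60.0
    #: optional per-algorithm grid overrides, e.g. {"SVM": {"C": [1], "gamma": [0.1]}}
    grids: dict = field(default_factory=dict)

    def validate(self) -> None:
        for alg in self.algorithms:
            if alg not in ALGORITHMS:
                raise ConfigError(f"unknown algorithm {alg!r}")
        for d in self.durations:
            if d not in (4, 8):
                raise ConfigError("durations must be 4 and/or 8")
        if not 0 < self.split_fraction < 1:
            raise ConfigError("split fraction must lie in (0, 1)")
        if self.selection_method not in (None, "BSTsel", "L1LRsel"):
            raise ConfigError("selection_method must be BSTsel, L1LRsel or None")
        if self.source not in PROFILES and not Path(self.source).is_dir():
            raise ConfigError(f"source {self.source!r} is neither a profile nor a directory")


def _stage_seeds(seed: int) -> dict:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(c.generate_state(1)[0] % (2**31 - 1))
        for name, c in zip(_STAGES, children)
    }


def _load_records(config: RunConfig, seed: int):
    if config.source in PROFILES:
        return gen_corpus(
            config.source,
            config.n_patients,
            config.records_per_patient,
            seed=seed,
            record_duration_s=config.record_duration_s,
        ).records
    return [
        sio.read_record_csv(p)
        for p in sorted(Path(config.source).glob("*.csv"))
        if not p.name.endswith(".ann.csv")
    ]


def single_feature_table(train, test) -> dict:
    """Per-feature maximum-likelihood threshold performance.

    Thresholds are fitted on the training rows (density crossing) and Se/Sp
    measured on the held-out test rows; features whose class densities never
    cross are reported as null entries.
    """
    out = {}
    for name in train.feature_names:
        tr_sh = train.X[name].to_numpy()[train.y == SH]
        tr_nsh = train.X[name].to_numpy()[train.y != SH]
        te_sh = test.X[name].to_numpy()[test.y == SH]
        te_nsh = test.X[name].to_numpy()[test.y != SH]
        try:
            clf = fit_ml_threshold(tr_sh, tr_nsh)
            m = clf.evaluate(te_sh, te_nsh)
        except (NoCrossingError, ValueError):
            out[name] = None
            continue
        out[name] = {
            "threshold": clf.threshold,
            "polarity": clf.polarity,
            "Se": m.se,
            "Sp": m.sp,
            "BER": m.ber,
        }
    return out


def run_study(config: RunConfig) -> dict:
    """Execute the full protocol; returns the results bundle (plain dict)."""
    config.validate()
    seeds = _stage_seeds(config.seed)
    bundle: dict = {"config": asdict(config), "seeds": seeds, "durations": {}}
    stage = "corpus"
    try:
        records = _load_records(config, seeds["corpus"])
        bundle["n_records"] = len(records)

        stage = "segment"
        datasets = {}
        for d in config.durations:
            segs, audits = [], []
            for rec in records:
                pre = preprocess_record(rec)
                segs.extend(segment_record(pre, d))
            kept, audit = label_and_filter(segs)
            log.info("duration %ds: %s", d, audit.as_dict())
            datasets[d] = (kept, audit)
            bundle["durations"][d] = {"audit": audit.as_dict()}

        stage = "features"
        features = {d: build_dataset(kept, d) for d, (kept, _) in datasets.items()}

        stage = "split"
        all_patients = np.unique(
            np.concatenate([ds.patients for ds in features.values()])
        )
        train_ids, test_ids = patient_split(
            all_patients, config.split_fraction, seeds["split"]
        )
        assert not set(train_ids) & set(test_ids), "leakage: split overlap"
        bundle["n_train_patients"] = len(train_ids)
        bundle["n_test_patients"] = len(test_ids)

        for d, ds in features.items():
            dres = bundle["durations"][d]
            train = ds.subset_patients(train_ids)
            test = ds.subset_patients(test_ids)
            assert not set(train.patients) & set(test.patients), "leakage"
            train_z, test_z = standardize(train, test)

            if config.single_features:
                stage = "single_features"
                dres["single_features"] = single_feature_table(train_z, test_z)

            stage = "selection"
            sel = None
            if config.selection_method is not None:
                rfe = rfe_bootstrap(
                    train_z,
                    config.selection_method,
                    B=config.selection_B,
                    seed=seeds["selection"],
                )
                sel = one_se_subset(rfe)
                dres["selection"] = {
                    "method": sel.method,
                    "k_s": sel.k_s,
                    "k_min": sel.k_min,
                    "subset": sel.subset,
                    "mean_ber_curve": sel.mean_ber.tolist(),
                    "se": sel.se,
                }

            dres["algorithms"] = {}
            for alg in config.algorithms:
                stage = "tune"
                spec = ModelSpec(alg, grid=config.grids.get(alg))
                hp = tune(spec, train_z, seed=seeds["tune"])

                stage = "fit"
                model = fit(spec, hp, train_z, seed=seeds["fit"])
                pred = predict(model, test_z.X)

                stage = "bootstrap"
                boot = bootstrap_metrics(
                    test_z.y, pred, test_z.patients, B=config.B, seed=seeds["bootstrap"]
                )
                point = metrics(test_z.y, pred)
                entry = {
                    "hyperparams": {k: v for k, v in hp.items() if not k.startswith("_")},
                    "point": point.as_dict(),
                    "bootstrap": boot.summary(),
                    "n_undefined_resamples": boot.n_undefined,
                }
                if sel is not None:
                    ev = evaluate_subset(
                        train_z, test_z, sel.subset, spec, hp,
                        B=config.B, seed=seeds["bootstrap"],
                    )
                    entry["subset_vs_all"] = {
                        "subset_metrics": ev.subset_metrics.as_dict(),
                        "delta_ber_mean": float(np.mean(ev.comparison.delta)),
                        "delta_ber_ci95": list(ev.comparison.ci95),
                        "significant": bool(ev.comparison.significant),
                    }
                dres["algorithms"][alg] = entry
    except Exception as err:  # annotate with the failing stage
        if isinstance(err, (ConfigError, StageError)):
            raise
        raise StageError(stage, bundle, err) from err

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for d, ds in features.items():
            sio.write_feature_table(ds, out / f"features_{d}s.csv")
        with open(out / "manifest.json", "w") as fh:
            json.dump(bundle, fh, indent=2, default=str)
    return bundle


def report(bundle: dict) -> str:
    """Human-readable summary of a results bundle.

    Prints per-algorithm Se/Sp/BER (one decimal, re-verifying the BER
    identity at print time), the selection curve summary and the chosen
    subsets in decreasing selection-count order.  An incomplete bundle lists
    its missing stages instead.
    """
    missing = [k for k in ("config", "durations") if k not in bundle]
    if missing:
        return "incomplete bundle; missing stages: " + ", ".join(missing)
    lines = []
    for d, dres in sorted(bundle["durations"].items()):
        lines.append(f"=== {d}-s segments ===")
        if "audit" in dres:
            lines.append(f"  exclusions: {dres['audit']}")
        singles = dres.get("single_features")
        if singles:
            ranked = sorted(
                (v["BER"], k, v) for k, v in singles.items() if v is not None
            )
            lines.append("  single-feature thresholds (best five by BER):")
            for ber, name, v in ranked[:5]:
                lines.append(
                    f"    {name:7s} Se {v['Se']:5.1f}  Sp {v['Sp']:5.1f}  "
                    f"BER {ber:5.1f}"
                )
        sel = dres.get("selection")
        if sel:
            lines.append(
                f"  {sel['method']}: K_s={sel['k_s']} (min at k={sel['k_min']}), "
                f"subset: {', '.join(sel['subset'])}"
            )
        for alg, entry in dres.get("algorithms", {}).items():
            se = entry["bootstrap"]["Se"]["mean"]
            sp = entry["bootstrap"]["Sp"]["mean"]
            ber = entry["bootstrap"]["BER"]["mean"]
            assert abs(ber - (100.0 - (se + sp) / 2.0)) < 1e-6, "BER identity"
            lines.append(f"  {alg:5s} Se {se:5.1f}  Sp {sp:5.1f}  BER {ber:5.1f}")
            sub = entry.get("subset_vs_all")
            if sub:
                lo, hi = sub["delta_ber_ci95"]
                star = "*" if sub["significant"] else ""
                lines.append(
                    f"        subset dBER {sub['delta_ber_mean']:+.1f} "
                    f"({lo:+.1f}, {hi:+.1f}){star}"
                )
    return "\n".join(lines)
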