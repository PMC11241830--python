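"""Configuration-driven orchestration of the three analyses.

``run_quantify`` / ``run_classify`` / ``run_authenticate`` wire the
library end to end the way the laboratory workflow does:

* quantify  — DUPLEX 120/60/60 split, PSO-tuned variable-weighted LS-SVM,
  figures of merit (recovery, r^2, RMSEP, LOD/LOQ) on the prediction set;
* classify  — dummy coding, LOO latent-variable selection, PLS2 fit on the
  training partition, argmax classification of the held-out partition;
* authenticate — OCPLS on genuine-class training samples (LV count by
  MCCV unless fixed), SD/ACR diagnostics and verdicts for queries.

Every entry point takes a seed and writes a run record sufficient to
regenerate its outputs bit-identically.  The numbered scripts under
``analysis/`` and the ``csarray`` command line both call these functions.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import datasets, ocpls, plsda, vwls
from .datasets import LabeledResponseSet, NoiseSpec
from .duplex import duplex_split
from .pso import PSOConfig

log = logging.getLogger(__name__)

DEFAULT_NOISE_FRACTION = 0.005  # replicate sd as a fraction of the max fingerprint amplitude
DEFAULT_SEPARATION_RATIO = 40.0  # min class separation over replicate sd


def synthetic_calibration_set(
    analyte: str, seed: int, noise_fraction: float = DEFAULT_NOISE_FRACTION
) -> LabeledResponseSet:
    """The standard quantitation study: 10 concentrations x 24 replicates."""
    fp = datasets.default_fingerprints()[analyte]
    sd = noise_fraction * float(np.abs(fp.max_response).max())
    return datasets.generate_single_analyte(
        fp,
        datasets.CALIBRATION_CONCENTRATIONS,
        datasets.DEFAULT_N_REPLICATES,
        NoiseSpec(replicate_sd=sd, seed=seed),
    )


def synthetic_mixture_grid_set(
    seed: int,
    analytes: tuple[str, str, str] = ("acetic", "hexanoic", "butyric"),
    separation_ratio: float = DEFAULT_SEPARATION_RATIO,
) -> LabeledResponseSet:
    """The mixed-acid study: 25 classes (fixed acetic 6 mmol/L, 5 x 5 grid),
    24 replicates, noise set from the minimum class separation."""
    lib = datasets.default_fingerprints()
    fps = [lib[a] for a in analytes]
    centroids = np.array(
        [
            datasets.mixture_expected_response(fps, (datasets.MIXTURE_FIXED_CONC, g1, g2))
            for g1 in datasets.MIXTURE_GRID
            for g2 in datasets.MIXTURE_GRID
        ]
    )
    sd = datasets.min_separation(centroids) / separation_ratio
    return datasets.generate_mixture_grid(
        fps,
        datasets.MIXTURE_FIXED_CONC,
        datasets.MIXTURE_GRID,
        datasets.DEFAULT_N_REPLICATES,
        NoiseSpec(replicate_sd=sd, seed=seed),
    )


def synthetic_spirit_population(
    seed: int,
    n_classes: int = 12,
    separation_ratio: float = DEFAULT_SEPARATION_RATIO,
) -> LabeledResponseSet:
    """A multi-class spirit-style population: pairwise-distinct fingerprint
    centroids with within-class Gaussian scatter, 24 replicates per class."""
    centroids = datasets.draw_class_centroids(n_classes, seed)
    sd = datasets.min_separation(centroids) / separation_ratio
    return datasets.generate_class_population(
        centroids, datasets.DEFAULT_N_REPLICATES, NoiseSpec(replicate_sd=sd, seed=seed)
    )


def synthetic_adulteration_study(
    seed: int,
    fractions: tuple[float, ...] = (0.5, 0.6, 0.7, 0.8, 0.9),
    n_train: int = 100,
    separation_ratio: float = DEFAULT_SEPARATION_RATIO,
) -> tuple[np.ndarray, LabeledResponseSet, LabeledResponseSet]:
    """Genuine-spirit training cloud plus volumetric adulterant blends.

    Two distinct spirit fingerprints are drawn; noise follows the
    separation rule.  Returns (training features, genuine query set,
    blend query set).
    """
    pure, adulterant = datasets.draw_class_centroids(2, seed)
    sd = float(np.linalg.norm(pure - adulterant)) / separation_ratio
    rng = np.random.default_rng(seed)
    train = pure + rng.normal(0, sd, (n_train, datasets.N_FEATURES))
    genuine = datasets.generate_adulteration(
        pure, adulterant, [0.0], datasets.DEFAULT_N_REPLICATES, NoiseSpec(sd, seed + 1)
    )
    blends = datasets.generate_adulteration(
        pure, adulterant, list(fractions), datasets.DEFAULT_N_REPLICATES, NoiseSpec(sd, seed + 2)
    )
    return train, genuine, blends


def run_quantify(
    data: LabeledResponseSet,
    seed: int = 0,
    ratios: tuple[float, float, float] = (0.5, 0.25, 0.25),
    pso: PSOConfig | None = None,
    log_target: bool = True,
    molar_mass_g_per_mol: float | None = None,
    blank_features: np.ndarray | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """DUPLEX split -> PSO-VWLS-SVM -> figures of merit on the prediction set."""
    if "concentration" not in data.labels:
        raise ValueError("quantify requires a 'concentration' label column")
    split = duplex_split(data.features, ratios)
    y = data.labels["concentration"].to_numpy(float)
    subsets = {
        name: (data.features[idx], y[idx])
        for name, idx in zip(("train", "monitor", "predict"), split.subsets())
    }
    if pso is None:
        lo, hi = vwls.default_pso_bounds(data.features.shape[1])
        pso = PSOConfig(bounds_lo=lo, bounds_hi=hi, seed=seed)
    model = vwls.train_pso_vwls_svm(
        subsets["train"], subsets["monitor"], pso=pso, log_target=log_target
    )
    fom = vwls.figures_of_merit(model, subsets["predict"])
    if blank_features is not None and molar_mass_g_per_mol is not None:
        lod, loq, sigma = vwls.lod_loq(blank_features, model, molar_mass_g_per_mol)
        fom.lod_g_per_l, fom.loq_g_per_l, fom.blank_sigma_mmol_l = lod, loq, sigma
    report = {
        "task": "quantify",
        "seed": int(seed),
        "split_sizes": list(split.sizes),
        "ratios": list(ratios),
        "log_target": bool(log_target),
        "pso": {
            "n_particles": pso.n_particles,
            "n_iterations": pso.n_iterations,
            "seed": pso.seed,
            "final_gbest": model.monitoring_rmse,
        },
        "kernel_width": model.spec.kernel_width,
        "reg_weight": model.spec.reg_weight,
        "weights": model.spec.weights.tolist(),
        **fom.to_dict(),
    }
    if out_dir is not None:
        _write_record(out_dir, "quantify", report, data.metadata)
    return {"report": report, "model": model, "split": split, "fom": fom}


def split_replicates(labels: pd.Series, fraction: float = 0.5) -> tuple[np.ndarray, np.ndarray]:
    """Per-class deterministic split: the first ``fraction`` of each class's
    replicates go to training, the rest to prediction."""
    labels = pd.Series(list(labels))
    train, predict = [], []
    for _, idx in labels.groupby(labels, sort=False).groups.items():
        idx = list(idx)
        cut = int(round(fraction * len(idx)))
        train.extend(idx[:cut])
        predict.extend(idx[cut:])
    return np.array(sorted(train)), np.array(sorted(predict))


def run_classify(
    data: LabeledResponseSet,
    label_column: str = "label",
    train_fraction: float = 0.5,
    max_lv: int | None = None,
    out_dir: str | Path | None = None,
) -> dict:
    """Dummy-code -> LOO LV selection -> PLS2 on training half -> argmax metrics."""
    labels = data.labels[label_column].tolist()
    if len(set(labels)) < 2:
        raise ValueError("classification requires at least 2 classes")
    tr, te = split_replicates(pd.Series(labels), train_fraction)
    X_tr, X_te = data.features[tr], data.features[te]
    y_tr = [labels[i] for i in tr]
    y_te = [labels[i] for i in te]
    cap = min(len(tr) - 2, data.features.shape[1])
    n_lv = plsda.loo_select_lv(X_tr, y_tr, max_lv or cap)
    model = plsda.pls2_fit(X_tr, plsda.encode_dummy(y_tr), n_lv)
    train_report = plsda.classification_metrics(y_tr, plsda.classify(model, X_tr))
    predict_report = plsda.classification_metrics(y_te, plsda.classify(model, X_te))
    report = {
        "task": "classify",
        "n_lv": int(n_lv),
        "n_train": len(tr),
        "n_predict": len(te),
        "train": train_report.to_dict(),
        "predict": predict_report.to_dict(),
    }
    if out_dir is not None:
        _write_record(out_dir, "classify", report, data.metadata)
        predict_report.confusion.to_csv(Path(out_dir) / "confusion_predict.csv")
    return {
        "report": report,
        "model": model,
        "n_lv": n_lv,
        "train_report": train_report,
        "predict_report": predict_report,
    }


def run_authenticate(
    genuine: np.ndarray | LabeledResponseSet,
    queries: np.ndarray | LabeledResponseSet,
    n_lv: int | None = None,
    confidence: float = 0.975,
    max_lv: int = 8,
    seed: int = 0,
    out_dir: str | Path | None = None,
) -> dict:
    """OCPLS fit on genuine samples, SD/ACR diagnostics + verdicts for queries."""
    X_g = genuine.features if isinstance(genuine, LabeledResponseSet) else np.asarray(genuine, float)
    X_q = queries.features if isinstance(queries, LabeledResponseSet) else np.asarray(queries, float)
    if len(X_q) and len(X_g):
        overlap = (X_q[:, None, :] == X_g[None, :, :]).all(axis=2).any()
        if overlap:
            log.warning("query set overlaps the genuine training set")
    if n_lv is None:
        n_lv = ocpls.mccv_select_lv(X_g, max_lv=max_lv, seed=seed)
    model = ocpls.ocpls_fit(X_g, n_lv=n_lv, confidence=confidence)
    verdicts, diags = ocpls.authenticate(model, X_q)
    table = pd.DataFrame(
        {
            "sd": [d.sd for d in diags],
            "acr": [d.acr for d in diags],
            "category": [d.category for d in diags],
            "genuine": verdicts,
        }
    )
    report = {
        "task": "authenticate",
        "n_lv": int(n_lv),
        "confidence": float(confidence),
        "sd_limit": model.sd_limit,
        "acr_limit": model.acr_limit,
        "n_queries": len(table),
        "n_genuine": int(table["genuine"].sum()),
        "n_flagged": int((~table["genuine"]).sum()),
    }
    if out_dir is not None:
        _write_record(out_dir, "authenticate", report, {})
        table.to_csv(Path(out_dir) / "diagnostics.csv", index=False)
        _plot_sd_acr(model, table, Path(out_dir) / "sd_acr.png")
    return {"report": report, "model": model, "diagnostics": table, "verdicts": verdicts}


def _plot_sd_acr(model, table: pd.DataFrame, path: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    for cat, sub in table.groupby("category"):
        ax.scatter(sub["sd"], sub["acr"], s=14, label=cat)
    ax.axvline(model.sd_limit, ls="--", c="k", lw=0.8)
    ax.axhline(model.acr_limit, ls="--", c="k", lw=0.8)
    ax.set_xlabel("score distance")
    ax.set_ylabel("absolute central residual")
    ax.legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def _write_record(out_dir, task: str, report: dict, metadata: dict) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / f"{task}_report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    if metadata:
        with open(out / f"{task}_data.yaml", "w") as fh:
            yaml.safe_dump(metadata, fh, sort_keys=False)


def run_from_config(config: dict) -> dict:
    """Dispatch a YAML-style config to the matching task."""
    task = config.get("task")
    seed = int(config.get("seed", 0))
    out_dir = config.get("out_dir")
    if task == "simulate":
        return _simulate_from_config(config)
    if task == "quantify":
        data = datasets.read_response_set(config["input"])
        return run_quantify(
            data,
            seed=seed,
            ratios=tuple(config.get("ratios", (0.5, 0.25, 0.25))),
            log_target=bool(config.get("log_target", True)),
            out_dir=out_dir,
        )
    if task == "classify":
        data = datasets.read_response_set(config["input"])
        return run_classify(
            data,
            label_column=config.get("label_column", "label"),
            train_fraction=float(config.get("train_fraction", 0.5)),
            max_lv=config.get("max_lv"),
            out_dir=out_dir,
        )
    if task == "authenticate":
        genuine = datasets.read_response_set(config["genuine"])
        queries = datasets.read_response_set(config["queries"])
        return run_authenticate(
            genuine,
            queries,
            n_lv=config.get("n_lv"),
            confidence=float(config.get("confidence", 0.975)),
            seed=seed,
            out_dir=out_dir,
        )
    raise ValueError(f"unknown task {task!r}")


def _simulate_from_config(config: dict) -> dict:
    kind = config.get("generator", "single_analyte")
    seed = int(config.get("seed", 0))
    noise = NoiseSpec(replicate_sd=float(config.get("replicate_sd", 0.0)), seed=seed)
    n_rep = int(config.get("n_rep", datasets.DEFAULT_N_REPLICATES))
    lib = datasets.default_fingerprints()
    if kind == "single_analyte":
        data = datasets.generate_single_analyte(
            lib[config["analyte"]],
            config.get("concentrations", list(datasets.CALIBRATION_CONCENTRATIONS)),
            n_rep,
            noise,
        )
    elif kind == "mixture_grid":
        fps = [lib[a] for a in config.get("analytes", ("acetic", "hexanoic", "butyric"))]
        data = datasets.generate_mixture_grid(
            fps,
            float(config.get("fixed_conc", datasets.MIXTURE_FIXED_CONC)),
            config.get("grid", list(datasets.MIXTURE_GRID)),
            n_rep,
            noise,
        )
    elif kind == "class_population":
        cents = np.asarray(
            config.get("centroids")
            if config.get("centroids") is not None
            else datasets.draw_class_centroids(int(config.get("n_classes", 12)), seed)
        )
        data = datasets.generate_class_population(cents, n_rep, noise)
    else:
        raise ValueError(f"unknown generator {kind!r}")
    out = config.get("output")
    if out:
        datasets.write_response_set(out, data)
    return {"data": data}
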