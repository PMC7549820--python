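"""Study-design dataset builders and the end-to-end pipeline.

Two study designs are reproduced at configurable scale:

* TdP-risk study — known compounds simulated at their effective free
  therapeutic plasma concentration (EFTPC), 20 heterogeneity/source
  repetitions each, 76 training + 10 validation compounds (1520 + 200
  samples at full scale), binary risk labels.
* Channel-block study — virtual compounds blocking one target channel
  (Na, K or Ca) at a random 0-50% level with 0-5% off-target block,
  140 samples by default, binary per-channel and ternary target labels.

Both builders run paired control/drug well simulations (the fast
surrogate backend by default; the full bidomain backend by config),
fit the wavelet part of the dictionary on the training split only, and
assemble the feature matrix.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import CostParams, CvConfig, GreedySparseLDA
from .compounds import CompoundSpec, ConductanceSet, reference_compound_table
from .features import FeatureDictionary, FeatureMatrix, build_feature_matrix
from .tissue import (ElectrodeModel, KLSampler, WellConfig, grid_preset,
                     simulate_well, simulate_well_pair)
from .validation import (aggregate_by_compound, confusion_and_metrics,
                         randomized_kfold)

logger = logging.getLogger(__name__)

CHANNEL_CLASSES = ("Na", "K", "Ca")


@dataclass(frozen=True)
class StudyConfig:
    """Configuration of one study run."""

    study: str = "tdp"                 # {tdp, channel_binary, channel_ternary}
    compounds_file: str | None = None  # None: packaged/synthetic table
    reps: int = 20                     # repetitions per compound
    n_channel_samples: int = 140       # channel-study database size
    grid: str = "6w9e"                 # device preset
    grid_nx: int = 21                  # grid resolution (nodes per side)
    concentration_policy: str = "eftpc"   # or "listed"
    backend: str = "surrogate"         # or "bidomain"
    scale: float = 1.0                 # desk-scale factor on compounds/reps
    seed: int = 0
    torsade_threshold: float = 0.03    # EFTPC/IC50_hERG rule of the
                                       # synthetic TdP label
    n_synthetic_compounds: int = 86
    with_calcium: bool = True
    dictionary: FeatureDictionary = field(default_factory=FeatureDictionary)

    def __post_init__(self):
        if self.reps < 1:
            raise ValueError("reps must be >= 1")
        if self.study not in ("tdp", "channel_binary", "channel_ternary"):
            raise ValueError(f"unknown study {self.study!r}")


@dataclass
class LabelledDataset:
    """Feature matrix plus task labels and a train/validation split."""

    features: FeatureMatrix
    labels: dict                       # task -> np.ndarray over samples
    split: np.ndarray                  # {"training", "validation"}

    @property
    def train_mask(self) -> np.ndarray:
        return self.split == "training"


# -------------------------------------------------- synthetic compounds

def synthetic_compound_table(n: int = 86, seed: int = 0,
                             torsade_threshold: float = 0.03,
                             n_validation: int = 10,
                             margin_gap: float = 4.0) -> list[CompoundSpec]:
    """Rule-labelled synthetic compound table (TdP study stand-in).

    IC50 triples and EFTPC are drawn log-uniformly over pharmacological
    ranges; a compound is labelled torsadogenic when its hERG safety
    margin EFTPC / IC50_hERG exceeds ``torsade_threshold`` — the
    classical margin-based risk rule. Draws whose margin lies within a
    factor ``margin_gap`` of the threshold are redrawn, so the label is
    always determined by a signal-visible hERG block (separable-label
    benchmark design); set ``margin_gap=1`` to disable the gap. The
    last ``n_validation`` compounds form the validation split.
    """
    if margin_gap < 1.0:
        raise ValueError("margin_gap must be >= 1")
    rng = np.random.default_rng(seed)
    out = []
    for i in range(n):
        while True:
            ic50 = {
                "hERG": float(10 ** rng.uniform(-2.5, 2.0)),
                "Cav1.2": float(10 ** rng.uniform(-2.0, 2.5)),
                "Nav1.5": float(10 ** rng.uniform(-2.0, 2.5)),
            }
            cmax = float(10 ** rng.uniform(-3.0, 1.5))
            margin = cmax / ic50["hERG"]
            if (margin <= torsade_threshold / margin_gap
                    or margin >= torsade_threshold * margin_gap):
                break
        risky = margin > torsade_threshold
        out.append(CompoundSpec(
            name=f"SYN-{i:03d}", ic50=ic50, hill=1.0,
            concentrations=(cmax,), cmax=cmax,
            tdp_label="risk" if risky else "no_risk",
            channel_labels=frozenset(),
            split="validation" if i >= n - n_validation else "training"))
    return out


# ------------------------------------------------------------- builders

def _well_config(cfg: StudyConfig) -> WellConfig:
    return WellConfig(backend=cfg.backend, with_calcium=cfg.with_calcium)


def build_tdp_dataset(compounds: list[CompoundSpec] | None,
                      config: StudyConfig | None = None) -> LabelledDataset:
    """Paired-well TdP dataset: one row per (compound, repetition).

    Compounds lacking an EFTPC are skipped with a log entry. Rows carry
    the binary risk label (+1 risk, -1 no risk); the split follows the
    compound table order.
    """
    cfg = config or StudyConfig(study="tdp")
    if compounds is None:
        compounds = synthetic_compound_table(
            max(2, int(round(cfg.n_synthetic_compounds * cfg.scale))),
            cfg.seed, cfg.torsade_threshold,
            n_validation=max(1, int(round(10 * cfg.scale))))
    reps = max(1, int(round(cfg.reps * cfg.scale)))
    grid = grid_preset(cfg.grid, nx=cfg.grid_nx)
    wc = _well_config(cfg)
    sampler = KLSampler(grid, wc.l_c)
    rng = np.random.default_rng(cfg.seed)

    pairs, labels, splits, names, concs = [], [], [], [], []
    for comp in compounds:
        if comp.cmax is None:
            logger.info("compound %s skipped: no EFTPC", comp.name)
            continue
        if comp.tdp_label == "unknown":
            logger.info("compound %s skipped: no TdP label", comp.name)
            continue
        for _ in range(reps):
            seed = int(rng.integers(0, 2 ** 31 - 1))
            pairs.append(simulate_well_pair(comp, comp.cmax, grid,
                                            seed=seed, config=wc,
                                            _sampler=sampler))
            labels.append(1 if comp.tdp_label == "risk" else -1)
            splits.append(comp.split)
            names.append(comp.name)
            concs.append(comp.cmax)

    split = np.array(splits)
    dictionary = replace_dictionary(cfg)
    dictionary.fit_wavelets([p for p, s in zip(pairs, split)
                             if s == "training"])
    fm = build_feature_matrix(pairs, dictionary,
                              train_mask=(split == "training"))
    kept = fm.provenance["sample_id"].to_numpy()
    return LabelledDataset(
        features=fm,
        labels={"tdp": np.asarray(labels)[kept]},
        split=split[kept])


def replace_dictionary(cfg: StudyConfig) -> FeatureDictionary:
    """Fresh dictionary instance honouring the study's calcium policy."""
    d = cfg.dictionary
    return FeatureDictionary(
        use_calcium=cfg.with_calcium and d.use_calcium,
        use_k_markers=d.use_k_markers, use_wavelets=d.use_wavelets,
        wavelet=d.wavelet, wavelet_threshold=d.wavelet_threshold,
        wavelet_level=d.wavelet_level, l2_tolerance=d.l2_tolerance,
        n_resample=d.n_resample, x_percent=d.x_percent, segment=d.segment)


def draw_channel_block(rng) -> tuple[str, ConductanceSet]:
    """One random single-target blockade draw.

    The target channel is uniform over {Na, K, Ca}; its conductance is
    blocked by Uniform(0, 50)% and the off-target channels by
    Uniform(0, 5)%.
    """
    target = CHANNEL_CLASSES[int(rng.integers(0, 3))]
    blocks = {ch: float(rng.uniform(0.0, 0.05)) for ch in CHANNEL_CLASSES}
    blocks[target] = float(rng.uniform(0.0, 0.50))
    scales = ConductanceSet(scale_na=1.0 - blocks["Na"],
                            scale_kr=1.0 - blocks["K"],
                            scale_ca=1.0 - blocks["Ca"])
    return target, scales


def build_channel_dataset(config: StudyConfig | None = None) -> LabelledDataset:
    """Random single-channel-blockade training database (default 140 rows).

    Labels: ``channel_ternary`` (target channel) and three binary
    per-channel tasks ``na``/``k``/``ca`` (+1 when that channel is the
    blocked target). An 80/20 train/validation split by sample order.
    """
    cfg = config or StudyConfig(study="channel_ternary", grid="96w8e")
    n = max(3, int(round(cfg.n_channel_samples * cfg.scale)))
    grid = grid_preset(cfg.grid if cfg.grid != "6w9e" else "96w8e",
                       nx=cfg.grid_nx)
    wc = _well_config(cfg)
    sampler = KLSampler(grid, wc.l_c)
    rng = np.random.default_rng(cfg.seed)

    pairs, targets = [], []
    for i in range(n):
        target, scales = draw_channel_block(rng)
        seed = int(rng.integers(0, 2 ** 31 - 1))
        ctrl = simulate_well(None, 0.0, grid, seed=seed, config=wc,
                             _sampler=sampler)
        drug = simulate_well(None, 0.0, grid, seed=seed, config=wc,
                             scales_override=scales,
                             virtual_name=f"block-{target}-{i:03d}",
                             _sampler=sampler)
        pairs.append((ctrl, drug))
        targets.append(target)

    targets = np.array(targets)
    n_train = int(round(0.8 * n))
    split = np.where(np.arange(n) < n_train, "training", "validation")
    dictionary = replace_dictionary(cfg)
    dictionary.fit_wavelets([p for p, s in zip(pairs, split)
                             if s == "training"])
    fm = build_feature_matrix(pairs, dictionary,
                              train_mask=(split == "training"))
    kept = fm.provenance["sample_id"].to_numpy()
    targets = targets[kept]
    labels = {"channel_ternary": targets}
    for ch in CHANNEL_CLASSES:
        labels[ch.lower()] = np.where(targets == ch, 1, -1)
    return LabelledDataset(features=fm, labels=labels, split=split[kept])


# ------------------------------------------------------------ run study

def run_study(config: StudyConfig, outdir,
              search: dict | None = None) -> dict:
    """End-to-end pipeline: dataset, dictionary, greedy training, reports.

    Writes the feature matrix, per-task model reports, confusion
    matrices for both splits and a run manifest under ``outdir``.
    Returns a summary dict (per task: training/validation metrics).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    search = search or {}
    stage = "dataset"
    try:
        if config.study == "tdp":
            compounds = (None if config.compounds_file is None else
                         _load(config.compounds_file))
            ds = build_tdp_dataset(compounds, config)
            tasks = {"tdp": ds.labels["tdp"]}
        else:
            ds = build_channel_dataset(config)
            if config.study == "channel_binary":
                tasks = {ch.lower(): ds.labels[ch.lower()]
                         for ch in CHANNEL_CLASSES}
            else:
                tasks = {"channel_ternary": ds.labels["channel_ternary"]}
        ds.features.labels = {k: pd.Series(v) for k, v in ds.labels.items()}
        ds.features.labels["split"] = pd.Series(ds.split)
        ds.features.to_files(outdir / "features")

        stage = "training"
        summary = {}
        for task, y in tasks.items():
            est = GreedySparseLDA(
                alpha=search.get("alpha", 2.0),
                beta=search.get("beta", 0.1),
                d_max=search.get("d_max", 2),
                n_comp_max=search.get("n_comp_max", 3),
                tol=search.get("tol", 0.05),
                optimizer=search.get("optimizer", "cmaes"),
                max_evals=search.get("max_evals", 60),
                cv_n_kfold=search.get("cv_n_kfold", 5),
                random_state=config.seed)
            tr = ds.train_mask
            Xtr = ds.features.values.loc[tr]
            est.fit(Xtr, y[tr])
            (outdir / f"model_{task}.txt").write_text(est.report() + "\n")
            np.savetxt(outdir / f"omega_{task}.csv", est.omega_,
                       delimiter=",",
                       header=",".join(ds.features.entry_names))

            stage = f"evaluation:{task}"
            rep_tr = confusion_and_metrics(y[tr], est.predict(Xtr),
                                           positive=1)
            entry = {"training": {"accuracy": rep_tr.accuracy,
                                  "sensitivity": rep_tr.sensitivity,
                                  "specificity": rep_tr.specificity}}
            if (~tr).any():
                Xva = ds.features.values.loc[~tr]
                pred_va = est.predict(Xva)
                rep_va = confusion_and_metrics(y[~tr], pred_va, positive=1)
                entry["validation"] = {"accuracy": rep_va.accuracy,
                                       "sensitivity": rep_va.sensitivity,
                                       "specificity": rep_va.specificity}
                rep_va.confusion.to_csv(outdir / f"confusion_{task}_val.csv")
                conf = est.predict_proba(Xva).max(axis=1)
                agg = aggregate_by_compound(
                    ds.features.provenance.loc[~tr], y[~tr], pred_va, conf)
                agg.to_csv(outdir / f"per_compound_{task}.csv", index=False)
            rep_tr.confusion.to_csv(outdir / f"confusion_{task}_train.csv")
            summary[task] = entry

        manifest = {
            "config": {k: str(v) for k, v in vars(config).items()},
            "search": search,
            "n_samples": ds.features.n_samples,
            "n_entries": len(ds.features.entry_names),
            "summary": summary,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
        return summary
    except Exception as exc:
        raise RuntimeError(f"study stage '{stage}' failed: {exc}") from exc


def _load(path):
    from .compounds import load_compound_table
    return load_compound_table(path)
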