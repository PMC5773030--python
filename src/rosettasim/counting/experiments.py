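"""Leaf-counting experiment drivers.

Three experiment designs probe how synthetic rosettes interact with the
counting task:

* **augmentation** — does adding 1000 synthetic rosettes (the S2 preset) to
  a real training set reduce counting error on real test images?
* **generalization** — can a network trained purely on the wide-range S12
  preset (mixed soil/random backgrounds) predict well on datasets whose
  leaf-count distributions each cover only part of that range?  Test
  images are preprocessed by blacking out their backgrounds with the
  foreground masks, so the network never sees uncontrolled backgrounds.
* **interoperability** — train on synthetic, test on real (or vice versa)
  within a matched leaf-count range; low error means the model is a
  usable stand-in for real plants.

Real phenotyping datasets are optional external inputs.  When none is
supplied, each driver runs a fully synthetic stand-in variant (S1 plays
the role of a narrow-range "real" set) and labels it as such in the
report; rows that fundamentally require external data are reported as
``external data required`` rather than failing.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional

import numpy as np

from ..dataset import iter_samples, load_dataset, preset, load_arrays
from ..render import apply_mask_black
from .metrics import EvalMetrics, round_half_away
from .model import CounterConfig, build_counter, evaluate, train

__all__ = ["ExperimentConfig", "ExperimentReport", "run_experiment", "train_size_sweep",
           "synthetic_arrays", "best_constant_agreement"]

EXPERIMENTS = ("augmentation", "generalization", "interoperability")


@dataclass(frozen=True)
class ExperimentConfig:
    counter: CounterConfig = field(default_factory=lambda: CounterConfig(input_size=128))
    n_images: int = 1000  # per synthetic dataset
    master_seed: int = 0
    split_seed: int = 0
    real_data_dir: Optional[str] = None  # external dataset: images + count CSV + masks
    out_dir: Optional[str] = None


@dataclass
class ExperimentReport:
    name: str
    rows: list  # dicts: train, test, metrics (EvalMetrics or None), note
    histograms: dict  # label -> (bin_edges, counts) of signed count differences

    def write(self, out_dir) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with open(out / f"{self.name}_metrics.csv", "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["Training data", "Testing data", "AbsCountDiff", "CountDiff",
                        "MSE", "R2", "Agreement (%)", "note"])
            for row in self.rows:
                m = row.get("metrics")
                cells = list(m.row().values()) if m else [""] * 5
                w.writerow([row["train"], row["test"], *cells, row.get("note", "")])
        for label, (edges, counts) in self.histograms.items():
            safe = label.replace("/", "-").replace(" ", "_")
            with open(out / f"{self.name}_hist_{safe}.csv", "w", newline="") as fh:
                w = csv.writer(fh)
                w.writerow(["bin_left", "bin_right", "count"])
                for lo, hi, c in zip(edges[:-1], edges[1:], counts):
                    w.writerow([lo, hi, c])


def synthetic_arrays(preset_name: str, cfg: ExperimentConfig,
                     background_mode: Optional[str] = None,
                     mask_black: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Render a synthetic preset in memory at the counter's input size."""
    spec = preset(preset_name, n_images=cfg.n_images, master_seed=cfg.master_seed,
                  image_size=cfg.counter.input_size)
    if background_mode is not None:
        spec = replace(spec, background_mode=background_mode)
    xs, ys = [], []
    for _i, sample, _params in iter_samples(spec):
        img = sample.image
        if mask_black:
            img = apply_mask_black(img, sample.mask)
        xs.append(img.astype(np.float32) / 255.0)
        ys.append(sample.leaf_count)
    return np.stack(xs), np.asarray(ys, dtype=np.float32)


def _split_arrays(x: np.ndarray, y: np.ndarray, fraction: float, seed: int):
    n_train = int(np.floor(fraction * len(x)))
    perm = np.random.default_rng(seed).permutation(len(x))
    tr, te = perm[:n_train], perm[n_train:]
    return (x[tr], y[tr]), (x[te], y[te])


def _real_arrays(cfg: ExperimentConfig, mask_black: bool = False):
    manifest = load_dataset(cfg.real_data_dir)
    return load_arrays(manifest, image_size=cfg.counter.input_size,
                       apply_black_mask=mask_black)


def _fit_eval(train_xy, test_xy, cfg: ExperimentConfig, seed_offset: int = 0):
    ccfg = replace(cfg.counter, seed=cfg.counter.seed + seed_offset)
    model = build_counter(ccfg)
    train(model, train_xy, ccfg, val_data=test_xy)
    metrics = evaluate(model, test_xy)
    return model, metrics


def _diff_histogram(model, test_xy) -> tuple[np.ndarray, np.ndarray]:
    x, y = test_xy
    d = round_half_away(model.predict(x)) - y
    lo, hi = int(d.min()), int(d.max())
    edges = np.arange(lo - 0.5, hi + 1.5)
    counts, _ = np.histogram(d, bins=edges)
    return edges, counts


def run_experiment(name: str, cfg: Optional[ExperimentConfig] = None) -> ExperimentReport:
    """Run one of the three experiment designs; returns (and optionally writes) a report."""
    cfg = cfg or ExperimentConfig()
    if name not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {name!r}; choose from {EXPERIMENTS}")
    report = ExperimentReport(name=name, rows=[], histograms={})
    frac = cfg.counter.split_fraction

    if name == "augmentation":
        s2 = synthetic_arrays("S2", cfg)
        if cfg.real_data_dir:
            real = _real_arrays(cfg)
            base_label = "real"
        else:
            # stand-in: the narrow-range S1 preset plays the role of the real set
            real = synthetic_arrays("S1", cfg)
            base_label = "S1 (synthetic stand-in for real)"
            report.rows.append({"train": "real + S2", "test": "real",
                                "metrics": None, "note": "external data required"})
        (rtr, rte) = _split_arrays(*real, frac, cfg.split_seed)
        model_plain, m_plain = _fit_eval(rtr, rte, cfg)
        aug_train = (np.concatenate([rtr[0], s2[0]]), np.concatenate([rtr[1], s2[1]]))
        model_aug, m_aug = _fit_eval(aug_train, rte, cfg, seed_offset=1)
        report.rows.append({"train": base_label, "test": base_label, "metrics": m_plain})
        report.rows.append({"train": f"{base_label} + S2", "test": base_label, "metrics": m_aug})
        report.histograms["augmented"] = _diff_histogram(model_aug, rte)

    elif name == "generalization":
        s12 = synthetic_arrays("S12", cfg)
        model = build_counter(cfg.counter)
        train(model, s12, cfg.counter)
        if cfg.real_data_dir:
            tests = [("real (masked black)", _real_arrays(cfg, mask_black=True))]
        else:
            tests = [
                ("S1 (masked black, stand-in)", synthetic_arrays("S1", cfg, mask_black=True)),
                ("S2 (masked black, stand-in)", synthetic_arrays("S2", cfg, mask_black=True)),
            ]
            report.rows.append({"train": "S12", "test": "real",
                                "metrics": None, "note": "external data required"})
        for label, xy in tests:
            m = evaluate(model, xy)
            report.rows.append({"train": "S12", "test": label, "metrics": m})
            report.histograms[label] = _diff_histogram(model, xy)

    else:  # interoperability
        s2 = synthetic_arrays("S2", cfg)
        if cfg.real_data_dir:
            real = _real_arrays(cfg)
            pairs = [("S2", s2, "real", real), ("real", real, "S2", s2)]
        else:
            s1 = synthetic_arrays("S1", cfg)
            pairs = [("S2", s2, "S1 (stand-in)", s1), ("S1 (stand-in)", s1, "S2", s2)]
            report.rows.append({"train": "S2", "test": "real",
                                "metrics": None, "note": "external data required"})
        for tr_label, tr_xy, te_label, te_xy in pairs:
            model, m = _fit_eval(tr_xy, te_xy, cfg)
            report.rows.append({"train": tr_label, "test": te_label, "metrics": m})
            report.histograms[f"{tr_label}->{te_label}"] = _diff_histogram(model, te_xy)
        # within-distribution baseline: S12 train/test split
        s12 = synthetic_arrays("S12", cfg)
        (ttr, tte) = _split_arrays(*s12, frac, cfg.split_seed)
        _model, m = _fit_eval(ttr, tte, cfg, seed_offset=2)
        report.rows.append({"train": "S12 (train split)", "test": "S12 (test split)", "metrics": m})

    if cfg.out_dir:
        report.write(cfg.out_dir)
    return report


def best_constant_agreement(labels: np.ndarray) -> float:
    """Agreement (%) of the best integer constant predictor for these labels."""
    labels = np.asarray(labels)
    vals, counts = np.unique(labels, return_counts=True)
    return float(100.0 * counts.max() / len(labels))


def train_size_sweep(
    sizes=(100, 250, 500, 1000),
    seeds=(0, 1, 2),
    cfg: Optional[ExperimentConfig] = None,
    test_size: int = 300,
) -> dict:
    """Test AbsCountDiff as a function of training-set size (median over seeds).

    A pool of ``max(sizes)`` S12 images is rendered once per seed; nested
    training subsets of each requested size are drawn from it and a fresh
    model is trained on each, always evaluated on the same held-out pool.
    """
    cfg = cfg or ExperimentConfig()
    results: dict = {s: [] for s in sizes}
    for seed in seeds:
        sweep_cfg = replace(cfg, master_seed=cfg.master_seed + 1000 * seed + 1,
                            n_images=max(sizes) + test_size)
        x, y = synthetic_arrays("S12", sweep_cfg)
        xte, yte = x[:test_size], y[:test_size]
        xtr, ytr = x[test_size:], y[test_size:]
        for s in sizes:
            ccfg = replace(cfg.counter, seed=cfg.counter.seed + seed)
            model = build_counter(ccfg)
            train(model, (xtr[:s], ytr[:s]), ccfg, val_data=(xte, yte))
            m = evaluate(model, (xte, yte))
            results[s].append(m.abs_count_diff_mean)
    medians = {s: float(np.median(v)) for s, v in results.items()}
    return {"sizes": list(sizes), "per_seed": results, "median_abs_count_diff": medians}
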