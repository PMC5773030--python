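"""Dataset presets, generation, loading and splitting.

The three shipped presets mirror the synthetic training sets used for the
counting experiments: 1000 images each at 256x256 with plant-diameter to
image-side ratios drawn from 0.5..1.0,

* ``S1``  — leaf counts 12..20, soil background;
* ``S2``  — leaf counts 5..13, soil background;
* ``S12`` — leaf counts 5..20, mixed soil/random-RGB background (p = 0.5).

A generated dataset directory contains ``plant_%05d_rgb.png`` images,
``plant_%05d_mask.png`` foreground masks, a ``labels.csv`` with header
``filename,leaf_count``, a ``manifest.csv`` with per-sample provenance,
``spec.yaml`` and ``params.yaml`` (per-sample rosette parameters, keyed by
filename).  Generation is reproducible: the per-sample seed is the tuple
``(master_seed, index, attempt)`` fed to a splittable seed sequence, so the
same spec always produces bit-identical files.

``load_dataset`` also accepts externally produced directories in the common
phenotyping layout (RGB image + leaf-count CSV + optional foreground mask
named ``*_mask.png``, ``*_label.png`` or ``*_fg.png``).
"""

from __future__ import annotations

import csv
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path
from typing import Iterator, Optional

import numpy as np
import yaml
from PIL import Image

from .curves import GrowthFunctionSet, default_function_set
from .render import InvisibleBladeError, LabeledSample, RenderConfig, render
from .rosette import RosetteParams, StochasticConfig, build_rosette, sample_rosette_params

__all__ = [
    "DatasetSpec",
    "SampleRecord",
    "DatasetManifest",
    "PRESETS",
    "preset",
    "generate_dataset",
    "iter_samples",
    "load_dataset",
    "split_train_test",
    "load_arrays",
]

_MAX_ATTEMPTS = 50


@dataclass(frozen=True)
class DatasetSpec:
    name: str
    n_images: int = 1000
    leaf_count_range: tuple[int, int] = (5, 20)
    background_mode: str = "soil"
    mixed_p: float = 0.5
    image_size: int = 256
    scale_ratio_range: tuple[float, float] = (0.5, 1.0)
    master_seed: int = 0

    def __post_init__(self):
        if self.n_images < 1:
            raise ValueError("n_images must be >= 1")

    def render_config(self) -> RenderConfig:
        return RenderConfig(
            image_size=self.image_size,
            scale_ratio_range=self.scale_ratio_range,
            background_mode=self.background_mode,
            mixed_p=self.mixed_p,
        )

    def stochastic_config(self) -> StochasticConfig:
        return StochasticConfig(leaf_count_range=self.leaf_count_range)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["leaf_count_range"] = list(self.leaf_count_range)
        d["scale_ratio_range"] = list(self.scale_ratio_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "DatasetSpec":
        d = dict(d)
        d["leaf_count_range"] = tuple(d["leaf_count_range"])
        d["scale_ratio_range"] = tuple(d["scale_ratio_range"])
        return cls(**d)


PRESETS: dict[str, DatasetSpec] = {
    "S1": DatasetSpec(name="S1", leaf_count_range=(12, 20), background_mode="soil"),
    "S2": DatasetSpec(name="S2", leaf_count_range=(5, 13), background_mode="soil"),
    "S12": DatasetSpec(name="S12", leaf_count_range=(5, 20), background_mode="mixed"),
}


def preset(name: str, **overrides) -> DatasetSpec:
    """A preset spec, optionally with overridden fields (n_images, master_seed, ...)."""
    if name not in PRESETS:
        raise KeyError(f"unknown preset {name!r}; choose from {sorted(PRESETS)}")
    return replace(PRESETS[name], **overrides)


@dataclass
class SampleRecord:
    filename: str
    leaf_count: int
    mask_filename: Optional[str] = None
    seed: Optional[str] = None
    background_kind: Optional[str] = None
    scale_ratio: Optional[float] = None


@dataclass
class DatasetManifest:
    root: Optional[Path]
    records: list
    spec: Optional[DatasetSpec] = None

    def __len__(self) -> int:
        return len(self.records)

    def leaf_counts(self) -> np.ndarray:
        return np.array([r.leaf_count for r in self.records], dtype=int)

    def image_path(self, r: SampleRecord) -> Path:
        return (self.root / r.filename) if self.root else Path(r.filename)

    def mask_path(self, r: SampleRecord) -> Optional[Path]:
        if r.mask_filename is None:
            return None
        return (self.root / r.mask_filename) if self.root else Path(r.mask_filename)


def _make_sample(spec: DatasetSpec, index: int, fs: GrowthFunctionSet,
                 render_images: bool) -> tuple[Optional[LabeledSample], RosetteParams, int]:
    """Build (and optionally render) sample ``index``; retries invisible blades."""
    scfg = spec.stochastic_config()
    rcfg = spec.render_config()
    for attempt in range(_MAX_ATTEMPTS):
        rng = np.random.default_rng(np.random.SeedSequence((spec.master_seed, index, attempt)))
        params = sample_rosette_params(scfg, rng)
        if not render_images:
            return None, params, attempt
        scene, _label = build_rosette(params, fs)
        try:
            sample = render(scene, rcfg, rng)
        except InvisibleBladeError:
            continue
        sample.params_ref = params
        return sample, params, attempt
    raise RuntimeError(f"sample {index}: no visible rendering in {_MAX_ATTEMPTS} attempts")


def iter_samples(spec: DatasetSpec, fs: Optional[GrowthFunctionSet] = None,
                 render_images: bool = True) -> Iterator[tuple[int, Optional[LabeledSample], RosetteParams]]:
    """Generate the dataset's samples in memory, in index order."""
    fs = fs or default_function_set()
    for i in range(spec.n_images):
        sample, params, _ = _make_sample(spec, i, fs, render_images)
        yield i, sample, params


def generate_dataset(spec: DatasetSpec, out_dir, fs: Optional[GrowthFunctionSet] = None,
                     render_images: bool = True) -> DatasetManifest:
    """Generate all samples of ``spec`` into ``out_dir``; returns the manifest.

    With ``render_images=False`` only labels, manifest, spec and parameter
    files are written (useful for label-distribution work at scale).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    records: list[SampleRecord] = []
    params_by_file: dict[str, dict] = {}
    for i, sample, params in iter_samples(spec, fs, render_images):
        stem = f"plant_{i:05d}"
        fname = f"{stem}_rgb.png"
        mname = f"{stem}_mask.png"
        if sample is not None:
            sample.save(out / fname, out / mname)
            rec = SampleRecord(fname, sample.leaf_count, mname, seed=f"{spec.master_seed}:{i}",
                               background_kind=sample.background_kind,
                               scale_ratio=sample.scale_ratio)
        else:
            rec = SampleRecord(fname, params.target_leaf_count, None, seed=f"{spec.master_seed}:{i}")
        records.append(rec)
        params_by_file[fname] = params.to_dict()

    with open(out / "labels.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "leaf_count"])
        for r in records:
            w.writerow([r.filename, r.leaf_count])
    with open(out / "manifest.csv", "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["filename", "mask_filename", "leaf_count", "seed", "background_kind", "scale_ratio"])
        for r in records:
            w.writerow([r.filename, r.mask_filename or "", r.leaf_count, r.seed or "",
                        r.background_kind or "", "" if r.scale_ratio is None else repr(r.scale_ratio)])
    with open(out / "spec.yaml", "w") as fh:
        yaml.safe_dump(spec.to_dict(), fh, sort_keys=False)
    with open(out / "params.yaml", "w") as fh:
        yaml.safe_dump(params_by_file, fh, default_flow_style=None, sort_keys=False)
    return DatasetManifest(root=out, records=records, spec=spec)


_MASK_SUFFIXES = ("_mask.png", "_label.png", "_fg.png")


def _find_mask(root: Path, filename: str) -> Optional[str]:
    stem = Path(filename).stem
    for base in (stem.replace("_rgb", ""), stem):
        for suf in _MASK_SUFFIXES:
            cand = f"{base}{suf}"
            if (root / cand).exists() and cand != filename:
                return cand
    return None


def load_dataset(path, check_files: bool = True) -> DatasetManifest:
    """Load a dataset directory (self-generated or external phenotyping layout)."""
    root = Path(path)
    if not root.is_dir():
        raise FileNotFoundError(f"dataset directory not found: {root}")

    spec = None
    if (root / "spec.yaml").exists():
        with open(root / "spec.yaml") as fh:
            spec = DatasetSpec.from_dict(yaml.safe_load(fh))

    manifest_csv = root / "manifest.csv"
    if manifest_csv.exists():
        records = []
        with open(manifest_csv, newline="") as fh:
            for lineno, row in enumerate(csv.DictReader(fh), start=2):
                records.append(SampleRecord(
                    filename=row["filename"],
                    leaf_count=_parse_count(row["leaf_count"], lineno, manifest_csv),
                    mask_filename=row.get("mask_filename") or None,
                    seed=row.get("seed") or None,
                    background_kind=row.get("background_kind") or None,
                    scale_ratio=float(row["scale_ratio"]) if row.get("scale_ratio") else None,
                ))
    else:
        csv_path = root / "labels.csv"
        if not csv_path.exists():
            candidates = sorted(root.glob("*.csv"))
            if not candidates:
                raise FileNotFoundError(f"no labels CSV found in {root}")
            csv_path = candidates[0]
        records = _read_label_csv(csv_path, root)

    if check_files:
        for r in records:
            p = root / r.filename
            if not p.exists():
                raise FileNotFoundError(f"label references missing image: {p}")
    return DatasetManifest(root=root, records=records, spec=spec)


def _parse_count(text: str, lineno: int, path) -> int:
    try:
        val = float(text)
        if not val.is_integer():
            raise ValueError
        return int(val)
    except ValueError:
        raise ValueError(f"{path}, line {lineno}: leaf count {text!r} is not an integer") from None


def _read_label_csv(csv_path: Path, root: Path) -> list:
    records = []
    with open(csv_path, newline="") as fh:
        rows = list(csv.reader(fh))
    start = 0
    if rows and rows[0] and not _is_intlike(rows[0][-1]):
        start = 1  # header row
    for lineno, row in enumerate(rows[start:], start=start + 1):
        if not row:
            continue
        fname, count = row[0].strip(), row[-1].strip()
        records.append(SampleRecord(
            filename=fname,
            leaf_count=_parse_count(count, lineno, csv_path),
            mask_filename=_find_mask(root, fname),
        ))
    return records


def _is_intlike(text: str) -> bool:
    try:
        return float(text).is_integer()
    except ValueError:
        return False


def split_train_test(manifest: DatasetManifest, fraction: float = 0.8,
                     seed: int = 0) -> tuple[DatasetManifest, DatasetManifest]:
    """Random disjoint exhaustive split; train size = floor(fraction * n)."""
    if not (0 < fraction < 1):
        raise ValueError("fraction must be in (0, 1)")
    n = len(manifest)
    n_train = int(np.floor(fraction * n))
    perm = np.random.default_rng(seed).permutation(n)
    train = [manifest.records[i] for i in sorted(perm[:n_train])]
    test = [manifest.records[i] for i in sorted(perm[n_train:])]
    return (DatasetManifest(manifest.root, train, manifest.spec),
            DatasetManifest(manifest.root, test, manifest.spec))


def load_arrays(manifest: DatasetManifest, image_size: Optional[int] = None,
                apply_black_mask: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Load images as float32 arrays in [0, 1] plus integer labels.

    ``apply_black_mask`` zeroes background pixels using each sample's
    foreground mask (the convention used when evaluating a model trained on
    synthetic images against externally photographed plants).
    """
    from .render import apply_mask_black

    xs, ys = [], []
    for r in manifest.records:
        img = Image.open(manifest.image_path(r)).convert("RGB")
        if apply_black_mask:
            mp = manifest.mask_path(r)
            if mp is None:
                raise ValueError(f"{r.filename}: black-background preprocessing needs a mask")
            mask = np.array(Image.open(mp).convert("L"))
            arr = apply_mask_black(np.array(img), (mask > 127).astype(np.uint8))
            img = Image.fromarray(arr)
        if image_size is not None and img.size != (image_size, image_size):
            img = img.resize((image_size, image_size), Image.BILINEAR)
        xs.append(np.asarray(img, dtype=np.float32) / 255.0)
        ys.append(r.leaf_count)
    return np.stack(xs), np.asarray(ys, dtype=np.float32)
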