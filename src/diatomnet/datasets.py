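"""Stratified 70/15/15 splitting and dataset manifests.

Splitting is per class: with ``n_c`` crops in class ``c``, the class
contributes ``floor(f_train * n_c)`` crops to training, ``floor(f_val * n_c)``
to validation, and the remainder to test; if a split would be empty for a
class with at least three crops, one crop is moved from that class's largest
split.  Assignment within a class is a seeded random permutation, so the
whole manifest is deterministic given (crops, fractions, seed).

By default the four flip variants of one source object travel together
(assigned as a group to a single split), which prevents near-duplicate
leakage between training and test.  Splitting variants independently is
available as an explicit option for protocols that augmented before
splitting.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np

from .preprocess import DiatomCrop

__all__ = ["ManifestRow", "DatasetManifest", "stratified_split", "write_manifest", "read_manifest"]

SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class ManifestRow:
    crop_id: str
    path: str  # file path, or "-" for in-memory crop sets
    species: str
    augmentation: str
    split: str


@dataclass(frozen=True)
class DatasetManifest:
    rows: tuple[ManifestRow, ...]
    seed: int
    grouped_variants: bool = True

    def __post_init__(self) -> None:
        ids = [r.crop_id for r in self.rows]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})[0]
            raise ValueError(f"duplicate crop_id in manifest: {dup!r}")
        for r in self.rows:
            if r.split not in SPLITS:
                raise ValueError(f"unknown split token {r.split!r} for crop {r.crop_id!r}")

    @property
    def class_table(self) -> dict[str, dict[str, int]]:
        """Per-class crop counts per split."""
        table: dict[str, dict[str, int]] = {}
        for r in self.rows:
            table.setdefault(r.species, {s: 0 for s in SPLITS})[r.split] += 1
        return table

    def split_ids(self, split: str) -> list[str]:
        if split not in SPLITS:
            raise ValueError(f"unknown split {split!r}; expected one of {SPLITS}")
        return [r.crop_id for r in self.rows if r.split == split]

    def validate_stratification(self, fractions=(0.70, 0.15, 0.15)) -> None:
        """Check the per-class one-unit bound on split fractions.

        The bound is one *assignment unit*: one crop when variants were split
        independently, one variant group (4 crops) when they were grouped.
        """
        unit = 4 if self.grouped_variants and any(r.augmentation != "original" for r in self.rows) else 1
        for species, counts in self.class_table.items():
            n = sum(counts.values())
            # floored splits land within one unit of target; the remainder
            # split absorbs both fractional parts (up to two units); repairing
            # an empty split for tiny classes can move one more
            repair = 0 if all(math.floor(f * n / unit) >= 1 for f in fractions) else unit
            for split, frac, base in zip(SPLITS, fractions, (unit, unit, 2 * unit)):
                if abs(counts[split] - frac * n) > base + repair + 1e-9:
                    raise ValueError(
                        f"class {species!r}: split {split} has {counts[split]}/{n}, "
                        f"more than one unit from the {frac:.2f} target"
                    )
            if n >= 3 and min(counts.values()) == 0:
                raise ValueError(f"class {species!r} missing from a split despite n={n}")


def _allocate(n: int, fractions: tuple[float, float, float]) -> list[int]:
    n_train = math.floor(fractions[0] * n)
    n_val = math.floor(fractions[1] * n)
    counts = [n_train, n_val, n - n_train - n_val]
    # guarantee every split is populated when the class is large enough
    if n >= 3:
        for i in range(3):
            if counts[i] == 0:
                counts[int(np.argmax(counts))] -= 1
                counts[i] += 1
    return counts


def stratified_split(
    crops: Sequence[DiatomCrop],
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
    seed: int = 0,
    group_variants: bool = True,
    paths: Optional[dict[str, str]] = None,
) -> DatasetManifest:
    """Assign crops to train/validation/test, stratified by species."""
    if not crops:
        raise ValueError("cannot split an empty crop list")
    if min(fractions) <= 0 or abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must be positive and sum to 1")
    rng = np.random.default_rng(seed)
    paths = paths or {}

    by_class: dict[str, list[DiatomCrop]] = {}
    for crop in crops:
        by_class.setdefault(crop.species, []).append(crop)

    assignment: dict[str, str] = {}
    for species in sorted(by_class):
        members = by_class[species]
        if group_variants:
            groups: dict[tuple, list[DiatomCrop]] = {}
            for crop in members:
                groups.setdefault(tuple(crop.source), []).append(crop)
            units = [groups[k] for k in sorted(groups)]
        else:
            units = [[c] for c in sorted(members, key=lambda c: c.crop_id)]
        if len(units) < 3:
            raise ValueError(
                f"class {species!r} has only {len(units)} assignable unit(s); "
                "need at least 3 to populate every split"
            )
        counts = _allocate(len(units), fractions)
        order = rng.permutation(len(units))
        bounds = np.cumsum(counts)
        for rank, unit_idx in enumerate(order):
            split = SPLITS[int(np.searchsorted(bounds, rank, side="right"))]
            for crop in units[unit_idx]:
                assignment[crop.crop_id] = split

    rows = tuple(
        ManifestRow(
            crop_id=c.crop_id,
            path=paths.get(c.crop_id, "-"),
            species=c.species,
            augmentation=c.augmentation,
            split=assignment[c.crop_id],
        )
        for c in crops
    )
    return DatasetManifest(rows=rows, seed=seed, grouped_variants=group_variants)


# ---------------------------------------------------------------------------
# manifest I/O: delimited text, one row per crop, stable order


def write_manifest(manifest: DatasetManifest, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="") as fh:
        fh.write(
            f"# diatomnet-manifest v1 seed={manifest.seed} "
            f"grouped_variants={int(manifest.grouped_variants)}\n"
        )
        writer = csv.writer(fh)
        writer.writerow(["crop_id", "path", "species", "augmentation", "split"])
        for r in manifest.rows:
            writer.writerow([r.crop_id, r.path, r.species, r.augmentation, r.split])
    return path


def read_manifest(path) -> DatasetManifest:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# diatomnet-manifest v1"):
            raise ValueError(f"{path}: not a diatomnet manifest")
        meta = dict(tok.split("=", 1) for tok in header.split()[3:])
        reader = csv.reader(fh)
        cols = next(reader)
        if cols != ["crop_id", "path", "species", "augmentation", "split"]:
            raise ValueError(f"{path}: unexpected manifest columns {cols}")
        rows = []
        for rec in reader:
            if len(rec) != 5:
                raise ValueError(f"{path}: malformed row {rec}")
            if not rec[1]:
                raise ValueError(f"{path}: missing file path for crop {rec[0]!r}")
            rows.append(ManifestRow(*rec))
    return DatasetManifest(
        rows=tuple(rows),
        seed=int(meta.get("seed", 0)),
        grouped_variants=bool(int(meta.get("grouped_variants", 1))),
    )
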