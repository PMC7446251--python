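"""Synthetic CNV cohorts with the statistics the classifier assumes.

The generator emulates sparse single-cell CNV profiles: each genome
carries on the order of one CNV, CNV positions concentrate on a
class-specific salient region with probability ``enrichment`` and fall
uniformly elsewhere, and both classes share the same CNV-count
distribution so that the raw normalization constants of the two class
vectors match in expectation (a validity condition of the metrics).

Per-sample CNV counts follow a zero-truncated Poisson with rate
``cnv_rate``: every genome carries at least one CNV, and at the default
rate of 1 most carry exactly one.  Windows are synthetic equal-width
tiles on a pseudo-chromosome ``chrS``; real coordinates are irrelevant
to the method.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .features import BinarySample
from .genome import GenomicWindows

LABEL_NAMES = {0: "disease", 1: "normal"}
LABEL_CODES = {"disease": 0, "normal": 1}


class CohortFormatError(ValueError):
    """A cohort TSV violates the sample-matrix contract."""


@dataclass(frozen=True)
class CohortSpec:
    """Study-condition parameters of a synthetic cohort.

    ``salient_regions`` gives, per class, the 1-based window index where
    that class's CNVs concentrate (default: region 1 for the disease
    class and the first region of the second genome half for the normal
    class); ``enrichment`` is the probability mass a CNV places there
    (0 = classes statistically identical, 1 = fully separable).
    """

    n_regions: int = 64
    samples_per_class: int = 10
    cnv_rate: float = 1.0
    salient_regions: tuple[int, int] | None = None
    enrichment: float = 0.8
    n_test_per_class: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_regions < 2:
            raise ValueError("need at least two regions")
        if self.samples_per_class < 1:
            raise ValueError("need at least one training sample per class")
        if not (0.0 <= self.enrichment <= 1.0):
            raise ValueError("enrichment must lie in [0, 1]")
        if self.cnv_rate <= 0:
            raise ValueError("cnv_rate must be positive")
        if self.salient_regions is None:
            object.__setattr__(self, "salient_regions", (1, self.n_regions // 2 + 1))
        for r in self.salient_regions:
            if not (1 <= r <= self.n_regions):
                raise ValueError(f"salient region {r} outside 1..{self.n_regions}")


@dataclass(frozen=True)
class Cohort:
    windows: GenomicWindows
    train: tuple[BinarySample, ...]
    test: tuple[BinarySample, ...]


def _truncated_poisson(rng: np.random.Generator, rate: float) -> int:
    """Poisson draw conditioned on being >= 1 (every genome has a CNV)."""
    while True:
        k = int(rng.poisson(rate))
        if k >= 1:
            return k


def _draw_sample(
    rng: np.random.Generator, spec: CohortSpec, label: int, sample_id: str
) -> BinarySample:
    bits = np.zeros(spec.n_regions, dtype=np.int64)
    salient = spec.salient_regions[label] - 1
    for _ in range(_truncated_poisson(rng, spec.cnv_rate)):
        if rng.random() < spec.enrichment:
            pos = salient
        else:
            pos = int(rng.integers(spec.n_regions))
        bits[pos] = 1
    return BinarySample(sample_id, bits, label=label)


def generate_cohort(spec: CohortSpec) -> Cohort:
    """Generate windows, labelled training samples and held-out test samples.

    Deterministic for a given ``spec.seed``.  Training samples alternate
    classes in the id order ``train_<class>_<index>``; held-out samples
    keep their true label for evaluation.
    """
    rng = np.random.default_rng(spec.seed)
    windows = GenomicWindows.tiles(spec.n_regions)
    train = [
        _draw_sample(rng, spec, label, f"train_{label}_{i}")
        for i in range(spec.samples_per_class)
        for label in (0, 1)
    ]
    test = [
        _draw_sample(rng, spec, label, f"test_{label}_{i}")
        for i in range(spec.n_test_per_class)
        for label in (0, 1)
    ]
    return Cohort(windows=windows, train=tuple(train), test=tuple(test))


def write_cohort(
    samples: Sequence[BinarySample],
    windows: GenomicWindows,
    bed_path: str | Path,
    tsv_path: str | Path,
) -> None:
    """Write windows as BED and the sample matrix as TSV.

    TSV columns: ``sample_id``, ``label`` (``disease``/``normal``, blank
    for unlabelled) then one {0, 1} column per window.
    """
    windows.to_bed(bed_path)
    cols = [f"w{i + 1}" for i in range(windows.N)]
    rows = []
    for s in samples:
        if len(s) != windows.N:
            raise CohortFormatError(
                f"sample {s.sample_id!r} has {len(s)} bits for {windows.N} windows"
            )
        label = "" if s.label is None else LABEL_NAMES[s.label]
        rows.append([s.sample_id, label, *s.bits.tolist()])
    df = pd.DataFrame(rows, columns=["sample_id", "label", *cols])
    df.to_csv(tsv_path, sep="\t", index=False)


def read_samples(
    tsv_path: str | Path,
    windows: GenomicWindows,
    binary: bool = True,
    baseline: int = 2,
) -> list[BinarySample]:
    """Read a sample matrix TSV against a window definition.

    With ``binary=True`` every matrix entry must be 0 or 1; otherwise
    entries are integer copy numbers binarized against ``baseline``.
    A ``label`` column is optional and may be blank per row.
    """
    from .features import binarize_profile

    df = pd.read_csv(tsv_path, sep="\t", dtype={"sample_id": str})
    if "sample_id" not in df.columns:
        raise CohortFormatError(f"{tsv_path}: missing 'sample_id' column")
    has_label = "label" in df.columns
    value_cols = [c for c in df.columns if c not in ("sample_id", "label")]
    if len(value_cols) != windows.N:
        raise CohortFormatError(
            f"{tsv_path}: {len(value_cols)} value columns for {windows.N} windows"
        )
    samples = []
    for idx, row in df.iterrows():
        label: int | None = None
        if has_label and not pd.isna(row["label"]) and str(row["label"]).strip():
            name = str(row["label"]).strip()
            if name not in LABEL_CODES:
                raise CohortFormatError(
                    f"{tsv_path} row {idx}: unknown label {name!r} (expected disease/normal)"
                )
            label = LABEL_CODES[name]
        values = row[value_cols].to_numpy()
        try:
            ints = np.asarray(values, dtype=np.int64)
        except (TypeError, ValueError) as exc:
            raise CohortFormatError(
                f"{tsv_path} row {idx} ({row['sample_id']}): non-integer entry"
            ) from exc
        if binary:
            bad = np.flatnonzero(~np.isin(ints, (0, 1)))
            if bad.size:
                col = value_cols[bad[0]]
                raise CohortFormatError(
                    f"{tsv_path} row {idx} ({row['sample_id']}), column {col}: "
                    f"value {ints[bad[0]]} is not binary"
                )
            samples.append(BinarySample(str(row["sample_id"]), ints, label=label))
        else:
            samples.append(
                binarize_profile(
                    ints, baseline=baseline, windows=windows,
                    sample_id=str(row["sample_id"]), label=label,
                )
            )
    return samples


def read_cohort(bed_path: str | Path, tsv_path: str | Path, binary: bool = True):
    """Round-trip counterpart of :func:`write_cohort`."""
    windows = GenomicWindows.from_bed(bed_path)
    return windows, read_samples(tsv_path, windows, binary=binary)
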