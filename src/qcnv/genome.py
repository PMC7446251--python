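"""Genomic windows: the feature dimensions of the classifier.

The genome is subdivided into N ordered, non-overlapping windows
(0-based, half-open coordinates, BED convention).  Window order defines
feature order: the n-qubit computational basis state |f_n ... f_1>
indexes region ``1 + sum_i f_i 2^(i-1)``, so 2^n basis states address up
to 2^n windows with n = ceil(log2(max(N, 2))) qubits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence


class BedFormatError(ValueError):
    """A BED record violates the coordinate or ordering contract."""


@dataclass(frozen=True)
class GenomicWindows:
    """Ordered, non-overlapping genomic windows.

    Parameters
    ----------
    windows
        Sequence of ``(chromosome, start, end)`` with 0-based half-open
        coordinates, sorted by ``(chromosome, start)`` and pairwise
        non-overlapping within a chromosome.
    """

    windows: tuple[tuple[str, int, int], ...] = field(default=())

    def __init__(self, windows: Iterable[Sequence]) -> None:
        wins = tuple((str(c), int(s), int(e)) for c, s, e in windows)
        if not wins:
            raise ValueError("at least one window is required")
        for chrom, start, end in wins:
            if start < 0 or start >= end:
                raise BedFormatError(
                    f"invalid interval {chrom}:{start}-{end}: require 0 <= start < end"
                )
        for (c1, s1, e1), (c2, s2, e2) in zip(wins, wins[1:]):
            if (c1, s1) > (c2, s2):
                raise BedFormatError(
                    f"windows not sorted by (chromosome, start) at {c2}:{s2}-{e2}"
                )
            if c1 == c2 and e1 > s2:
                raise BedFormatError(
                    f"overlapping windows {c1}:{s1}-{e1} and {c2}:{s2}-{e2}"
                )
        object.__setattr__(self, "windows", wins)

    @property
    def N(self) -> int:
        """Number of windows (feature dimensions)."""
        return len(self.windows)

    @property
    def n(self) -> int:
        """Qubits needed to index the windows: ceil(log2(max(N, 2)))."""
        return max(1, math.ceil(math.log2(self.N)))

    @property
    def padded_size(self) -> int:
        """2^n, the number of computational basis states."""
        return 1 << self.n

    def region_index(self, bits: Sequence[int]) -> int:
        """1-based region index of the basis state |f_n ... f_1>.

        ``bits`` lists (f_1, ..., f_n), least-significant first.
        """
        return 1 + sum(int(f) << i for i, f in enumerate(bits))

    @classmethod
    def tiles(cls, n_windows: int, width: int = 1000, chrom: str = "chrS") -> "GenomicWindows":
        """Equal-width tiles on a single pseudo-chromosome."""
        return cls([(chrom, i * width, (i + 1) * width) for i in range(n_windows)])

    @classmethod
    def from_bed(cls, path: str | Path) -> "GenomicWindows":
        """Read windows from a BED file (3 columns minimum)."""
        wins = []
        with open(path) as fh:
            for lineno, line in enumerate(fh, start=1):
                line = line.strip()
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                if len(fields) < 3:
                    raise BedFormatError(f"{path} line {lineno}: fewer than 3 columns")
                chrom, start, end = fields[0], fields[1], fields[2]
                try:
                    start_i, end_i = int(start), int(end)
                except ValueError as exc:
                    raise BedFormatError(
                        f"{path} line {lineno}: non-integer coordinates"
                    ) from exc
                if start_i >= end_i:
                    raise BedFormatError(
                        f"{path} line {lineno}: start >= end ({start_i} >= {end_i})"
                    )
                wins.append((chrom, start_i, end_i))
        return cls(wins)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for chrom, start, end in self.windows:
                fh.write(f"{chrom}\t{start}\t{end}\n")
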