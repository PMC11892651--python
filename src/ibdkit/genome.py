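"""Genetic maps of the autosomes.

All public coordinates are in centimorgans (cM); model internals convert to
Morgans in one place (:mod:`ibdkit.split_model`). The bundled default map
carries sex-averaged HapMap-style lengths for the 22 human autosomes
(total ~3546 cM).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

_DEFAULT_MAP_RESOURCE = "genome_map_hapmap37.tsv"


@dataclass(frozen=True)
class GenomeMap:
    """Ordered mapping of autosome index -> genetic length in cM."""

    lengths: Mapping[int, float]
    _chroms: tuple[int, ...] = field(init=False, repr=False)
    _lengths_cm: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.lengths:
            raise ValueError("genome map must contain at least one chromosome")
        chroms = tuple(sorted(int(c) for c in self.lengths))
        arr = np.asarray([float(self.lengths[c]) for c in chroms])
        if np.any(arr <= 0) or not np.all(np.isfinite(arr)):
            raise ValueError("all chromosome lengths must be finite and > 0")
        object.__setattr__(self, "lengths", dict(zip(chroms, arr.tolist())))
        object.__setattr__(self, "_chroms", chroms)
        object.__setattr__(self, "_lengths_cm", arr)

    @property
    def chroms(self) -> tuple[int, ...]:
        return self._chroms

    @property
    def lengths_cm(self) -> np.ndarray:
        """Lengths as an array ordered by chromosome index."""
        return self._lengths_cm.copy()

    @property
    def lengths_morgan(self) -> np.ndarray:
        return self._lengths_cm / 100.0

    @property
    def total_cM(self) -> float:
        return float(self._lengths_cm.sum())

    @property
    def max_cM(self) -> float:
        return float(self._lengths_cm.max())

    def __len__(self) -> int:
        return len(self._chroms)

    def __getitem__(self, chrom: int) -> float:
        return self.lengths[int(chrom)]

    def __contains__(self, chrom: int) -> bool:
        return int(chrom) in self.lengths

    @classmethod
    def from_lengths(cls, lengths_cm: Iterable[float]) -> "GenomeMap":
        """Build from a sequence of lengths, numbering chromosomes 1..n."""
        return cls({i + 1: float(l) for i, l in enumerate(lengths_cm)})

    @classmethod
    def from_tsv(cls, path: str | Path) -> "GenomeMap":
        df = pd.read_csv(path, sep="\t", comment="#")
        missing = {"chrom", "length_cm"} - set(df.columns)
        if missing:
            raise ValueError(f"genome map file missing column(s): {sorted(missing)}")
        return cls(dict(zip(df["chrom"].astype(int), df["length_cm"].astype(float))))

    @classmethod
    def default(cls) -> "GenomeMap":
        """The bundled 22-autosome sex-averaged map."""
        ref = resources.files("ibdkit.data") / _DEFAULT_MAP_RESOURCE
        with resources.as_file(ref) as path:
            return cls.from_tsv(path)

    def to_tsv(self, path: str | Path) -> None:
        pd.DataFrame(
            {"chrom": self._chroms, "length_cm": self._lengths_cm}
        ).to_csv(path, sep="\t", index=False)
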