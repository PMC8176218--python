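"""Core domain types shared across the pipeline.

All genomic coordinates are 0-based, half-open.  The TTS of a minus-strand
gene is its interval *start*; the TSS is its interval *end*.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np
import pandas as pd


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class ConfigError(ValueError):
    """Invalid configuration value."""


@dataclass(frozen=True)
class GeneModel:
    """A stranded gene body with optional exon/CDS structure.

    ``exons`` are genomic intervals sorted by start; ``cds`` is a single
    genomic interval (start, end) or ``None`` for non-coding genes.
    """

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    cds: tuple[int, int] | None = None
    gc: float = float("nan")

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError(f"{self.gene_id}: start must be < end")
        if self.strand not in ("+", "-"):
            raise InputError(f"{self.gene_id}: strand must be '+' or '-'")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def tss(self) -> int:
        """Transcription start coordinate (position of the first transcribed base)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tts(self) -> int:
        """3' boundary coordinate: ``end`` on plus strand, ``start`` on minus."""
        return self.end if self.strand == "+" else self.start

    @property
    def three_prime_base(self) -> int:
        """Genomic position of the last transcribed base."""
        return self.end - 1 if self.strand == "+" else self.start

    def utr3_interval(self, default_len: int = 500) -> tuple[int, int]:
        """Genomic interval of the 3' non-coding region.

        Uses the annotated CDS boundary when present, otherwise the final
        ``default_len`` nt of the gene body.
        """
        if self.cds is not None:
            if self.strand == "+":
                return (self.cds[1], self.end)
            return (self.start, self.cds[0])
        n = min(default_len, self.length)
        if self.strand == "+":
            return (self.end - n, self.end)
        return (self.start, self.start + n)


@dataclass(frozen=True)
class TranscribedSegment:
    """A contiguous interval called transcribed on one strand in one state."""

    chrom: str
    start: int
    end: int
    strand: str
    state: str
    mean_coverage: float

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise InputError("segment start must be < end")
        if self.mean_coverage <= 0:
            raise InputError("segment mean coverage must be > 0")

    @property
    def length(self) -> int:
        return self.end - self.start


class CoverageTrack:
    """Strand-specific, non-negative per-base coverage over a set of chromosomes.

    Data are dense float arrays keyed by ``(chrom, strand)``; absent keys
    read as all-zero.
    """

    def __init__(self, chrom_lengths: dict[str, int]):
        self.chrom_lengths = dict(chrom_lengths)
        self._data: dict[tuple[str, str], np.ndarray] = {}

    def get(self, chrom: str, strand: str) -> np.ndarray:
        key = (chrom, strand)
        if key not in self._data:
            self._data[key] = np.zeros(self.chrom_lengths[chrom], dtype=float)
        return self._data[key]

    def keys(self) -> Iterator[tuple[str, str]]:
        for chrom in self.chrom_lengths:
            for strand in "+-":
                yield chrom, strand

    def add(self, other: "CoverageTrack") -> None:
        if other.chrom_lengths != self.chrom_lengths:
            raise InputError("coverage tracks have mismatched chromosome lengths")
        for key, arr in other._data.items():
            self.get(*key)[:] += arr

    def total(self) -> float:
        """Total coverage mass, used for library-size normalization."""
        return float(sum(arr.sum() for arr in self._data.values()))

    def copy(self) -> "CoverageTrack":
        out = CoverageTrack(self.chrom_lengths)
        for key, arr in self._data.items():
            out._data[key] = arr.copy()
        return out


def make_design(
    states: Iterable[str],
    replicates_per_state: int,
    days_below_threshold: dict[str, float] | None = None,
) -> pd.DataFrame:
    """Build a sample sheet for a state x replicate design.

    Sex alternates within each state so the covariate is balanced; the
    optional ``days_below_threshold`` map fills the Tb-below-8C metadata
    column used by the elongation-rate arithmetic.
    """
    rows = []
    for state in states:
        for rep in range(1, replicates_per_state + 1):
            rows.append(
                {
                    "sample": f"{state}_{rep}",
                    "state": state,
                    "replicate": rep,
                    "sex": "F" if rep % 2 else "M",
                    "days_below_8": (
                        float("nan")
                        if days_below_threshold is None
                        else days_below_threshold.get(state, float("nan"))
                    ),
                }
            )
    return pd.DataFrame(rows)


@dataclass
class PatternLibrary:
    """Named template vectors of relative expression over an ordered state list."""

    states: tuple[str, ...]
    templates: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.states = tuple(self.states)
        if len(set(self.states)) != len(self.states):
            raise ConfigError("pattern library states must be unique")
        clean = {}
        for name, vec in self.templates.items():
            v = np.asarray(vec, dtype=float)
            if v.shape != (len(self.states),):
                raise ConfigError(f"template {name!r} has wrong length")
            if np.allclose(v, v[0]):
                raise ConfigError(f"template {name!r} has zero variance")
            clean[name] = v
        self.templates = clean

    def names(self) -> list[str]:
        return list(self.templates)

    def __len__(self) -> int:
        return len(self.templates)


def rna_pattern_library() -> PatternLibrary:
    """Default 14-template library over (SA, IBA, Ent, Ar, SpD).

    Template values are declared defaults: Pearson-based assignment only
    depends on ordinal shape, not absolute levels.
    """
    states = ("SA", "IBA", "Ent", "Ar", "SpD")
    t = {
        "Winter_high": [0, 1, 1, 1, 0],
        "Winter_low": [1, 0, 0, 0, 1],
        "Cold_high_EH": [0, 0, 1, 1, 0],
        "Cold_high_EM": [0, 0, 0.5, 1, 0],
        "Cold_high_EL": [0, 0, 0, 1, 0],
        "Cold_low_EH": [1, 1, 0, 0, 1],
        "Cold_low_EM": [1, 1, 0.5, 0, 1],
        "Cold_low_EL": [1, 1, 1, 0, 1],
        "IBA_high": [0, 1, 0, 0, 0],
        "IBA_low": [1, 0, 1, 1, 1],
        "SA_high": [1, 0, 0, 0, 0],
        "SA_low": [0, 1, 1, 1, 1],
        "SpD_high": [0, 0, 0, 0, 1],
        "SpD_low": [1, 1, 1, 1, 0],
    }
    return PatternLibrary(states, {k: np.asarray(v, float) for k, v in t.items()})


def nascent_pattern_library() -> PatternLibrary:
    """Default 6-template library over (SA, IBA, Ent, ET, LT); declared defaults."""
    states = ("SA", "IBA", "Ent", "ET", "LT")
    t = {
        "Cold_high_EM": [0, 0, 0.5, 1, 1],
        "Cold_low_EM": [1, 1, 0.5, 0, 0],
        "IBA_high": [0, 1, 0, 0, 0],
        "IBA_low": [1, 0, 1, 1, 1],
        "SA_high": [1, 0, 0, 0, 0],
        "SA_low": [0, 1, 1, 1, 1],
    }
    return PatternLibrary(states, {k: np.asarray(v, float) for k, v in t.items()})
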