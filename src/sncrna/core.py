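"""Core data containers shared across the pipeline.

Coordinates are 0-based half-open internally (BED convention). TSV table
fixtures that mirror printed supplementary tables use 1-based inclusive
coordinates; conversion happens at the I/O boundary only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

#: sncRNA classes handled by the annotator, in tie-break priority order.
SNCRNA_CLASSES = ("miRNA", "tRNA", "YRNA", "rRNA", "snRNA", "snoRNA")

CLASS_PRIORITY = {c: i for i, c in enumerate(SNCRNA_CLASSES)}

UNANNOTATED = "unannotated"

#: Read-length window retained after preprocessing (nt).
MIN_READ_LEN = 18
MAX_READ_LEN = 48


class InputError(ValueError):
    """Malformed or inconsistent user input."""


class DegenerateInputError(InputError):
    """Structurally valid input on which the statistic is undefined."""


@dataclass(frozen=True)
class GenomicFeature:
    """An annotated sncRNA locus (miRNA hairpin, tRNA gene, Y RNA gene, ...)."""

    feature_id: str
    sncrna_class: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # exclusive
    strand: str
    display_name: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise InputError(
                f"feature {self.feature_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"feature {self.feature_id!r}: bad strand {self.strand!r}")
        if self.sncrna_class not in SNCRNA_CLASSES:
            raise InputError(
                f"feature {self.feature_id!r}: unknown class {self.sncrna_class!r}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        """Genomic position of the biological 5' terminus (0-based)."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class AlignmentRecord:
    """A genome-aligned, adapter-trimmed read (identical reads collapsed)."""

    read_id: str
    chrom: str
    start: int
    end: int
    strand: str
    multiplicity: int = 1

    def __post_init__(self):
        if self.start >= self.end:
            raise InputError(
                f"alignment {self.read_id!r}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise InputError(f"alignment {self.read_id!r}: bad strand {self.strand!r}")
        if self.multiplicity < 1:
            raise InputError(f"alignment {self.read_id!r}: multiplicity < 1")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def five_prime(self) -> int:
        return self.start if self.strand == "+" else self.end - 1

    @property
    def three_prime(self) -> int:
        return self.end - 1 if self.strand == "+" else self.start


@dataclass(frozen=True)
class ClassifiedRead:
    """An alignment with its assigned feature, class and 5'/3' end label."""

    alignment: AlignmentRecord
    feature_id: str | None
    sncrna_class: str
    end_label: str = "none"  # five_prime | three_prime | none

    def __post_init__(self):
        if (self.feature_id is None) != (self.sncrna_class == UNANNOTATED):
            raise InputError("feature_id is None iff class is 'unannotated'")
        if self.end_label not in ("five_prime", "three_prime", "none"):
            raise InputError(f"bad end label {self.end_label!r}")
        if self.end_label != "none" and self.sncrna_class not in ("tRNA", "YRNA"):
            raise InputError("end labels apply only to tRNA/YRNA assignments")


@dataclass
class ClassProfile:
    """Per-class read-length histogram with class totals and percentages."""

    counts: dict  # (class, length) -> int
    totals: dict  # class -> int
    percentages: dict  # class -> float, over annotated classes, sums to 100


@dataclass
class CountMatrix:
    """Feature x sample integer count matrix with two-group labels.

    ``counts`` is features-by-samples; ``lib_sizes`` defaults to column sums.
    """

    feature_ids: list
    sample_ids: list
    counts: np.ndarray
    group: dict  # sample -> "case" | "control"
    lib_sizes: dict = field(default_factory=dict)

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.shape != (len(self.feature_ids), len(self.sample_ids)):
            raise InputError(
                f"count matrix shape {self.counts.shape} does not match "
                f"{len(self.feature_ids)} features x {len(self.sample_ids)} samples"
            )
        if np.any(self.counts < 0):
            raise InputError("negative counts")
        if not self.lib_sizes:
            self.lib_sizes = dict(
                zip(self.sample_ids, self.counts.sum(axis=0).astype(int).tolist())
            )
        for s in self.sample_ids:
            if s not in self.group:
                raise InputError(f"sample {s!r} has no group label")

    @property
    def lib_size_array(self) -> np.ndarray:
        return np.array([self.lib_sizes[s] for s in self.sample_ids], dtype=float)

    def group_mask(self, which: str) -> np.ndarray:
        return np.array([self.group[s] == which for s in self.sample_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.feature_ids, columns=self.sample_ids)

    def to_tsv(self, path) -> None:
        df = self.to_frame()
        df.index.name = "feature_id"
        df.to_csv(path, sep="\t")

    @classmethod
    def from_tsv(cls, counts_path, group: Mapping[str, str]) -> "CountMatrix":
        df = pd.read_csv(counts_path, sep="\t", index_col=0)
        return cls(
            feature_ids=list(df.index),
            sample_ids=list(df.columns),
            counts=df.to_numpy(dtype=np.int64),
            group=dict(group),
        )


@dataclass
class SimulationTruth:
    """Ground truth planted by the synthetic-data generators."""

    da_features: set = field(default_factory=set)
    true_log2fc: dict = field(default_factory=dict)
    true_dispersion: float = 0.0
    overtargeted_genes: set = field(default_factory=set)
    seed: int = 0


@dataclass
class DAResult:
    """One row of a differential-abundance table.

    ``fc_signed`` follows the printed-table convention: sign(log2fc) * 2^|log2fc|,
    so -3.4 means 3.4-fold down. ``avg_cpm`` is the mean CPM over all libraries.
    """

    feature_id: str
    avg_cpm: float
    log2fc: float
    fc_signed: float
    pvalue: float
    fdr: float
    significant: bool = False


@dataclass(frozen=True)
class CohortRecord:
    """One subject of the case/control cohort."""

    subject_id: str
    group: str  # case | control
    age: int
    tnm: str | None = None
    localization: str | None = None

    @property
    def t_stage(self) -> int | None:
        from .clinical import parse_t_stage

        return parse_t_stage(self.tnm) if self.tnm else None


def signed_fold_change(log2fc: float) -> float:
    """Map log2 fold change to the signed-FC convention of printed DA tables."""
    if log2fc == 0:
        return 1.0
    return float(np.sign(log2fc) * 2.0 ** abs(log2fc))


def check_seed(seed) -> int:
    seed = int(seed)
    if seed < 0:
        raise InputError("seed must be non-negative")
    return seed


def ordered_classes(classes: Sequence[str]) -> list:
    """Sort classes by the fixed annotation priority (unknowns last)."""
    return sorted(classes, key=lambda c: CLASS_PRIORITY.get(c, len(CLASS_PRIORITY)))
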