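"""Classification of genome-aligned reads into sncRNA classes.

Reads are assigned to the same-strand feature with maximal overlap (at least
``min_overlap_frac`` of the read length); antisense overlaps never count,
since sncRNA fragments are strand-specific by biogenesis. Ties are broken by
overlap length, then class priority miRNA > tRNA > YRNA > rRNA > snRNA >
snoRNA, then lowest feature id, so every read gets a single deterministic
assignment (mirroring a best-single-alignment mapping policy).

5' tRNA halves are 30-33 nt fragments retaining the tRNA's 5' terminus;
YRNA-derived small RNAs retain either the 5' or the 3' terminus of the
parent gene, and the end of origin is a biological label carried through to
the DA tables.
"""

from __future__ import annotations

from collections import defaultdict

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .core import (
    UNANNOTATED,
    AlignmentRecord,
    ClassifiedRead,
    ClassProfile,
    CLASS_PRIORITY,
    CountMatrix,
    DegenerateInputError,
    GenomicFeature,
    InputError,
    ordered_classes,
)

DEFAULT_MIN_OVERLAP_FRAC = 0.5
DEFAULT_END_WINDOW = 5
DEFAULT_TRNA_SIZE_RANGE = (30, 33)
DEFAULT_START_TOLERANCE = 1


def _build_index(annotation: list) -> dict:
    trees: dict[tuple, IntervalTree] = defaultdict(IntervalTree)
    for f in annotation:
        trees[(f.chrom, f.strand)].addi(f.start, f.end, f)
    return trees


def assign_yrna_end(
    read: AlignmentRecord, feature: GenomicFeature, end_window: int = DEFAULT_END_WINDOW
) -> str:
    """Label a read as 5'- or 3'-derived relative to its parent feature.

    A read is ``five_prime`` when its biological 5' terminus lies within
    ``end_window`` nt of the feature's 5' terminus (strand-aware), and
    ``three_prime`` analogously; if both or neither end qualifies the label
    is ``none`` (ambiguous).
    """
    if read.strand != feature.strand:
        raise InputError(
            f"read {read.read_id!r} strand {read.strand} does not match "
            f"feature {feature.feature_id!r} strand {feature.strand}"
        )
    five = abs(read.five_prime - feature.five_prime) <= end_window
    three = abs(read.three_prime - feature.three_prime) <= end_window
    if five and not three:
        return "five_prime"
    if three and not five:
        return "three_prime"
    return "none"


def classify_reads(
    alignments: list,
    annotation: list,
    min_overlap_frac: float = DEFAULT_MIN_OVERLAP_FRAC,
    end_window: int = DEFAULT_END_WINDOW,
) -> list:
    """Assign each alignment to its best same-strand feature.

    Returns one :class:`ClassifiedRead` per input alignment, in input order.
    tRNA and YRNA assignments carry an end label from :func:`assign_yrna_end`.
    """
    if not annotation:
        raise InputError("annotation is empty")
    if not 0 < min_overlap_frac <= 1:
        raise InputError("min_overlap_frac must be in (0, 1]")
    for rec in alignments:
        if rec.start >= rec.end:
            raise InputError(f"alignment {rec.read_id!r}: start >= end")
    trees = _build_index(annotation)
    out = []
    for rec in alignments:
        tree = trees.get((rec.chrom, rec.strand))
        best = None
        if tree is not None:
            candidates = []
            for iv in tree.overlap(rec.start, rec.end):
                feat: GenomicFeature = iv.data
                overlap = min(rec.end, feat.end) - max(rec.start, feat.start)
                if overlap >= min_overlap_frac * rec.length:
                    candidates.append((overlap, feat))
            if candidates:
                best = min(
                    candidates,
                    key=lambda c: (-c[0], CLASS_PRIORITY[c[1].sncrna_class], c[1].feature_id),
                )[1]
        if best is None:
            out.append(ClassifiedRead(rec, None, UNANNOTATED))
        else:
            end_label = "none"
            if best.sncrna_class in ("tRNA", "YRNA"):
                end_label = assign_yrna_end(rec, best, end_window)
            out.append(ClassifiedRead(rec, best.feature_id, best.sncrna_class, end_label))
    return out


def length_distribution(classified: list) -> ClassProfile:
    """Multiplicity-weighted (class, read length) histogram with class totals."""
    counts: dict = defaultdict(int)
    totals: dict = defaultdict(int)
    for cr in classified:
        w = cr.alignment.multiplicity
        counts[(cr.sncrna_class, cr.alignment.length)] += w
        totals[cr.sncrna_class] += w
    annotated_total = sum(v for k, v in totals.items() if k != UNANNOTATED)
    percentages = {}
    if annotated_total:
        percentages = {
            c: 100.0 * t / annotated_total for c, t in totals.items() if c != UNANNOTATED
        }
    return ClassProfile(counts=dict(counts), totals=dict(totals), percentages=percentages)


def class_proportions(classified: list) -> dict:
    """Percentage of annotated reads per class (multiplicity-weighted)."""
    profile = length_distribution(classified)
    if not profile.percentages:
        raise DegenerateInputError("no annotated reads")
    return profile.percentages


def compare_class_distribution(counts_a: dict, counts_b: dict):
    """Pearson chi-square test of independence on the class x group table.

    Returns ``(chi2, df, p)`` with no continuity correction; degrees of
    freedom are (k - 1) for k classes with nonzero totals.
    """
    classes = [
        c
        for c in ordered_classes(set(counts_a) | set(counts_b))
        if counts_a.get(c, 0) + counts_b.get(c, 0) > 0
    ]
    if len(classes) < 2:
        raise DegenerateInputError("need >= 2 classes with nonzero totals")
    table = np.array(
        [[counts_a.get(c, 0) for c in classes], [counts_b.get(c, 0) for c in classes]],
        dtype=float,
    )
    if table.sum(axis=1).min() == 0:
        raise DegenerateInputError("one group has zero total reads")
    expected = stats.contingency.expected_freq(table)
    if np.any(expected == 0):
        raise DegenerateInputError("expected cell count of zero")
    chi2, p, df, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), int(df), float(p)


def count_trna_halves(
    classified: list,
    annotation: list,
    size_range: tuple = DEFAULT_TRNA_SIZE_RANGE,
    start_tolerance: int = DEFAULT_START_TOLERANCE,
) -> dict:
    """Count 5' tRNA halves per tRNA locus.

    Only tRNA-classified reads whose length falls in ``size_range`` and whose
    5' terminus lies within ``start_tolerance`` nt of the feature's 5'
    terminus are counted (multiplicity-weighted). 3' tRNA fragments are
    deliberately not counted.
    """
    if start_tolerance < 0:
        raise InputError("start_tolerance must be >= 0")
    lo, hi = size_range
    feats = {f.feature_id: f for f in annotation}
    out: dict = defaultdict(int)
    for cr in classified:
        if cr.sncrna_class != "tRNA" or cr.feature_id is None:
            continue
        if not lo <= cr.alignment.length <= hi:
            continue
        feat = feats.get(cr.feature_id)
        if feat is None:
            raise InputError(f"classified read references unknown feature {cr.feature_id!r}")
        if abs(cr.alignment.five_prime - feat.five_prime) <= start_tolerance:
            out[cr.feature_id] += cr.alignment.multiplicity
    return dict(out)


def aggregate_counts(
    classified: list,
    samples: dict,
    class_filter: str,
    end_filter: str | None = None,
    group: dict | None = None,
) -> CountMatrix:
    """Build a feature x sample count matrix from classified reads.

    ``samples`` maps read id -> sample id; rows are features of
    ``class_filter`` (optionally restricted to one end label), cells are
    multiplicity-weighted read counts.
    """
    sample_ids = sorted(set(samples.values()))
    cell: dict = defaultdict(int)
    features = set()
    for cr in classified:
        rid = cr.alignment.read_id
        if rid not in samples:
            raise InputError(f"read {rid!r} has no sample assignment")
        if cr.sncrna_class != class_filter:
            continue
        if end_filter is not None and cr.end_label != end_filter:
            continue
        features.add(cr.feature_id)
        cell[(cr.feature_id, samples[rid])] += cr.alignment.multiplicity
    feature_ids = sorted(features)
    counts = np.zeros((len(feature_ids), len(sample_ids)), dtype=np.int64)
    for i, f in enumerate(feature_ids):
        for j, s in enumerate(sample_ids):
            counts[i, j] = cell.get((f, s), 0)
    group = group or {s: "case" for s in sample_ids}
    return CountMatrix(feature_ids, sample_ids, counts, group=dict(group))
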