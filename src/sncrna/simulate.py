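"""Synthetic-data generators with planted ground truth.

Every generator is a pure function of its arguments including ``seed`` (one
fresh ``numpy`` Generator per call; no global RNG state), so identical calls
are byte-identical. The defaults emulate a 7-vs-7 serum small-RNA-seq
case/control design: negative-binomial counts with sample-specific library
sizes, class-composition shifts between groups, planted fold changes of the
magnitudes seen in serum DA tables, and miRNA-target universes with planted
overtargeted genes.

Sequence-level simulation is out of scope: alignment simulation ends at
BED-style interval records, with no FASTQ, error model or adapter content.
"""

from __future__ import annotations

import math

import numpy as np

from .core import (
    AlignmentRecord,
    CohortRecord,
    CountMatrix,
    GenomicFeature,
    InputError,
    SimulationTruth,
    check_seed,
)
from .overtargeting import InteractionUniverse

#: Default class mix of annotated serum reads (miRNA-dominated, YRNA second).
DEFAULT_CLASS_MIX = {"miRNA": 0.50, "YRNA": 0.38, "tRNA": 0.10, "rRNA": 0.02}

#: Default read-length profiles: miRNAs peak at 20-24 nt, tRNA halves at
#: 30-33 nt, YRNA fragments at 25-33 nt.
DEFAULT_LENGTH_PROFILES = {
    "miRNA": {20: 0.10, 21: 0.20, 22: 0.40, 23: 0.20, 24: 0.10},
    "tRNA": {30: 0.25, 31: 0.30, 32: 0.25, 33: 0.20},
    "YRNA": {25: 0.10, 26: 0.15, 27: 0.20, 28: 0.15, 29: 0.10, 30: 0.10, 31: 0.10, 32: 0.10, 33: 0.10},
    "rRNA": {18: 0.2, 19: 0.2, 20: 0.2, 21: 0.2, 22: 0.2},
    "snRNA": {20: 0.5, 21: 0.5},
    "snoRNA": {20: 0.5, 21: 0.5},
}

#: Default per-sample library-size range. Serum small-RNA libraries vary
#: widely and depth is rarely reported; sizes are drawn log-uniform in this
#: window and the window is exposed as a parameter.
DEFAULT_LIBSIZE_RANGE = (1_000_000, 5_000_000)


def gen_count_matrix(
    n_features: int,
    n_per_group: int,
    frac_da: float,
    log2fc_magnitude: float,
    dispersion: float,
    libsize_range: tuple = DEFAULT_LIBSIZE_RANGE,
    seed: int = 0,
) -> tuple[CountMatrix, SimulationTruth]:
    """Simulate an NB feature-by-sample count matrix with planted effects.

    Baseline feature log-means are uniform on [log 5, log 5000] (spanning the
    CPM range of low- through very-high-abundance serum fragments); library
    sizes are log-uniform within ``libsize_range`` and enter as offsets. A
    random ``frac_da`` subset of features receives a +/- ``log2fc_magnitude``
    shift in the case group, sign drawn 50/50 per feature. Counts are
    NB(mean mu, variance mu + dispersion * mu^2).
    """
    seed = check_seed(seed)
    if n_features <= 0:
        raise InputError("n_features must be positive")
    if n_per_group < 2:
        raise InputError("need >= 2 samples per group")
    if dispersion <= 0:
        raise InputError("dispersion must be positive")
    if not 0 <= frac_da <= 1:
        raise InputError("frac_da must be in [0, 1]")
    lo, hi = libsize_range
    if not (0 < lo <= hi):
        raise InputError("libsize_range must be ordered positive")

    rng = np.random.default_rng(seed)
    n_samples = 2 * n_per_group
    base_mean = np.exp(rng.uniform(math.log(5.0), math.log(5000.0), size=n_features))
    lib_sizes = np.exp(rng.uniform(math.log(lo), math.log(hi), size=n_samples))
    lib_sizes = np.round(lib_sizes).astype(int)
    # library-size offsets relative to the mean library
    offsets = lib_sizes / lib_sizes.mean()

    n_da = int(round(frac_da * n_features))
    da_idx = rng.choice(n_features, size=n_da, replace=False) if n_da else np.array([], int)
    signs = rng.choice([-1.0, 1.0], size=n_da)
    log2fc = np.zeros(n_features)
    log2fc[da_idx] = signs * log2fc_magnitude

    is_case = np.arange(n_samples) < n_per_group
    mu = base_mean[:, None] * offsets[None, :]
    mu = mu * np.where(is_case[None, :], 2.0 ** log2fc[:, None], 1.0)

    # NB parameterised by size r = 1/dispersion: var = mu + mu^2/r
    r = 1.0 / dispersion
    p = r / (r + mu)
    counts = rng.negative_binomial(r, p)

    sample_ids = [f"T{i + 1}" for i in range(n_per_group)] + [
        f"N{i + 1}" for i in range(n_per_group)
    ]
    feature_ids = [f"feat{i:05d}" for i in range(n_features)]
    group = {s: ("case" if flag else "control") for s, flag in zip(sample_ids, is_case)}
    m = CountMatrix(
        feature_ids=feature_ids,
        sample_ids=sample_ids,
        counts=counts.astype(np.int64),
        group=group,
        lib_sizes=dict(zip(sample_ids, lib_sizes.tolist())),
    )
    truth = SimulationTruth(
        da_features={feature_ids[i] for i in da_idx},
        true_log2fc={feature_ids[i]: float(log2fc[i]) for i in da_idx},
        true_dispersion=float(dispersion),
        seed=seed,
    )
    return m, truth


def gen_annotation(
    n_per_class: dict | None = None,
    feature_length: dict | None = None,
    spacing: int = 200,
    seed: int = 0,
) -> list:
    """Lay out non-overlapping features per class on one synthetic chromosome.

    Strands alternate so strand-aware logic is exercised; non-overlap makes
    the classification round-trip exact.
    """
    seed = check_seed(seed)
    n_per_class = n_per_class or {"miRNA": 50, "YRNA": 20, "tRNA": 30, "rRNA": 5}
    feature_length = feature_length or {
        "miRNA": 70, "YRNA": 100, "tRNA": 73, "rRNA": 120, "snRNA": 100, "snoRNA": 80,
    }
    rng = np.random.default_rng(seed)
    features = []
    pos = 1000
    entries = []
    for cls, n in n_per_class.items():
        entries.extend((cls, i) for i in range(n))
    rng.shuffle(entries)
    for cls, i in entries:
        length = feature_length[cls]
        strand = "+" if rng.random() < 0.5 else "-"
        features.append(
            GenomicFeature(
                feature_id=f"{cls}_{i:03d}",
                sncrna_class=cls,
                chrom="chrS",
                start=pos,
                end=pos + length,
                strand=strand,
                display_name=f"{cls}-{i}",
            )
        )
        pos += length + spacing
    return features


def _sample_length(rng, profile: dict) -> int:
    lengths = np.array(sorted(profile))
    probs = np.array([profile[l] for l in lengths], dtype=float)
    probs = probs / probs.sum()
    return int(rng.choice(lengths, p=probs))


def gen_alignments(
    annotation: list,
    n_reads: int,
    class_mix: dict | None = None,
    length_profiles: dict | None = None,
    seed: int = 0,
) -> list:
    """Place synthetic reads inside annotated features according to a class mix.

    tRNA reads start at the feature's 5' terminus (strand-aware), emulating
    5' tRNA halves; YRNA reads are anchored at a randomly chosen feature end;
    miRNA and other reads sit at the feature 5' end clipped to the feature.
    """
    seed = check_seed(seed)
    class_mix = class_mix or dict(DEFAULT_CLASS_MIX)
    length_profiles = length_profiles or DEFAULT_LENGTH_PROFILES
    if n_reads < 0:
        raise InputError("n_reads must be non-negative")
    if abs(sum(class_mix.values()) - 1.0) > 1e-9:
        raise InputError("class_mix fractions must sum to 1")
    by_class: dict[str, list] = {}
    for f in annotation:
        by_class.setdefault(f.sncrna_class, []).append(f)
    for cls in class_mix:
        if not by_class.get(cls):
            raise InputError(f"class {cls!r} has no features in the annotation")
    if n_reads == 0:
        return []

    rng = np.random.default_rng(seed)
    classes = sorted(class_mix)
    probs = np.array([class_mix[c] for c in classes], dtype=float)
    probs /= probs.sum()
    assigned = rng.choice(len(classes), size=n_reads, p=probs)
    reads = []
    for i, ci in enumerate(assigned):
        cls = classes[ci]
        feats = by_class[cls]
        feat = feats[int(rng.integers(len(feats)))]
        length = _sample_length(rng, length_profiles[cls])
        length = min(length, feat.length)
        if cls == "tRNA":
            anchor = "five_prime"
        elif cls == "YRNA":
            anchor = "five_prime" if rng.random() < 0.5 else "three_prime"
        else:
            anchor = "five_prime"
        if anchor == "five_prime":
            if feat.strand == "+":
                start = feat.start
            else:
                start = feat.end - length
        else:
            if feat.strand == "+":
                start = feat.end - length
            else:
                start = feat.start
        reads.append(
            AlignmentRecord(
                read_id=f"r{i:06d}",
                chrom=feat.chrom,
                start=int(start),
                end=int(start + length),
                strand=feat.strand,
                multiplicity=1,
            )
        )
    return reads


def gen_universe(
    n_mirnas: int,
    n_genes: int,
    density: float,
    n_planted: int,
    da_set: set | None = None,
    boost: float = 4.0,
    seed: int = 0,
) -> tuple[InteractionUniverse, SimulationTruth]:
    """Simulate a miRNA-gene interaction universe with planted overtargeting.

    Non-planted genes receive an edge from each miRNA independently with
    probability ``density``; planted genes receive edges from DA miRNAs with
    probability ``min(1, density * boost)`` (and from non-DA miRNAs at the
    base density), so under ``boost=1`` planted and background genes are
    statistically indistinguishable.
    """
    seed = check_seed(seed)
    if not 0 <= density <= 1:
        raise InputError("density must be in [0, 1]")
    if n_planted > n_genes:
        raise InputError("n_planted exceeds n_genes")
    if boost < 1:
        raise InputError("boost must be >= 1")
    mirnas = [f"MIR-{i:03d}" for i in range(n_mirnas)]
    genes = [f"GENE{j:04d}" for j in range(n_genes)]
    # the real universe is built from the DA miRNAs' own target predictions
    # plus validated pairs, so DA miRNAs make up a large share of it; half is
    # the emulated default
    da_set = set(da_set) if da_set is not None else set(mirnas[: max(1, n_mirnas // 2)])
    unknown = da_set - set(mirnas)
    if unknown:
        raise InputError(f"da_set contains miRNAs outside the universe: {sorted(unknown)[:3]}")

    rng = np.random.default_rng(seed)
    planted = set(genes[:n_planted])
    edges = set()
    boosted = min(1.0, density * boost)
    for g in genes:
        for m in mirnas:
            p = boosted if (g in planted and m in da_set) else density
            if rng.random() < p:
                edges.add((m, g))
    provenance = rng.random(len(edges))  # a slice of edges marked validated
    universe = InteractionUniverse.from_edges(
        predicted={e for e, r in zip(sorted(edges), provenance) if r >= 0.1},
        validated={e for e, r in zip(sorted(edges), provenance) if r < 0.1},
    )
    truth = SimulationTruth(
        da_features=set(da_set),
        overtargeted_genes=planted,
        seed=seed,
    )
    return universe, truth


def gen_cohort(
    n_cases: int,
    n_controls: int,
    age_range: tuple = (45, 70),
    t_stages: list | None = None,
    seed: int = 0,
) -> list:
    """Simulate a case/control cohort table (age, TNM string, localization)."""
    seed = check_seed(seed)
    t_stages = list(t_stages) if t_stages else []
    if t_stages and len(t_stages) != n_cases:
        raise InputError("t_stages must be empty or one per case")
    rng = np.random.default_rng(seed)
    lo, hi = age_range
    records = []
    localizations = ["Oral", "Oropharynx", "Larynx"]
    for i in range(n_cases):
        t = t_stages[i] if t_stages else int(rng.integers(1, 5))
        if not 1 <= t <= 4:
            raise InputError(f"invalid T stage {t}")
        n = int(rng.integers(0, min(t, 3) + 1))
        records.append(
            CohortRecord(
                subject_id=f"T{i + 1}",
                group="case",
                age=int(rng.integers(lo, hi + 1)),
                tnm=f"T{t}N{n}M0",
                localization=localizations[int(rng.integers(len(localizations)))],
            )
        )
    for i in range(n_controls):
        records.append(
            CohortRecord(
                subject_id=f"N{i + 1}",
                group="control",
                age=int(rng.integers(lo, hi + 1)),
            )
        )
    return records
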