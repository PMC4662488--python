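"""Plain-text readers and writers: BED6 alignments, TSV annotation,
count/DA/cohort tables, two-column interaction tables and gene lists."""

from __future__ import annotations

import pandas as pd

from .core import AlignmentRecord, GenomicFeature, InputError


def write_bed(alignments: list, path) -> None:
    """BED6: chrom, start, end, name, score=read multiplicity, strand."""
    with open(path, "w") as fh:
        for a in alignments:
            fh.write(f"{a.chrom}\t{a.start}\t{a.end}\t{a.read_id}\t{a.multiplicity}\t{a.strand}\n")


def read_bed(path) -> list:
    out = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 6:
                raise InputError(f"{path}:{i + 1}: expected 6 BED columns")
            chrom, start, end, name, score, strand = parts[:6]
            out.append(
                AlignmentRecord(
                    read_id=name,
                    chrom=chrom,
                    start=int(start),
                    end=int(end),
                    strand=strand,
                    multiplicity=max(1, int(float(score))),
                )
            )
    return out


_ANN_COLS = ["feature_id", "sncrna_class", "chrom", "start", "end", "strand", "display_name"]


def write_annotation(features: list, path) -> None:
    rows = [
        {
            "feature_id": f.feature_id,
            "sncrna_class": f.sncrna_class,
            "chrom": f.chrom,
            "start": f.start,
            "end": f.end,
            "strand": f.strand,
            "display_name": f.display_name,
        }
        for f in features
    ]
    pd.DataFrame(rows, columns=_ANN_COLS).to_csv(path, sep="\t", index=False)


def read_annotation(path) -> list:
    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    missing = set(_ANN_COLS[:-1]) - set(df.columns)
    if missing:
        raise InputError(f"annotation missing columns: {sorted(missing)}")
    return [
        GenomicFeature(
            feature_id=str(r.feature_id),
            sncrna_class=str(r.sncrna_class),
            chrom=str(r.chrom),
            start=int(r.start),
            end=int(r.end),
            strand=str(r.strand),
            display_name=str(getattr(r, "display_name", "")),
        )
        for r in df.itertuples()
    ]


def write_da_results(results: list, path) -> None:
    rows = [
        {
            "id": r.feature_id,
            "cpm": round(r.avg_cpm, 1),
            "fc": round(r.fc_signed, 1),
            "log2fc": r.log2fc,
            "pvalue": r.pvalue,
            "fdr": r.fdr,
            "significant": r.significant,
        }
        for r in results
    ]
    pd.DataFrame(
        rows, columns=["id", "cpm", "fc", "log2fc", "pvalue", "fdr", "significant"]
    ).to_csv(path, sep="\t", index=False)


def read_da_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def read_pairs(path) -> set:
    """Two-column TSV of (miRNA, gene) pairs; header optional."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    if df.shape[1] < 2:
        raise InputError(f"{path}: expected 2 columns")
    first = tuple(df.iloc[0])
    if first[0].lower() in ("mirna", "mir", "mirna_id"):
        df = df.iloc[1:]
    return {(str(a), str(b)) for a, b in zip(df[0], df[1])}


def read_gene_list(path) -> set:
    with open(path) as fh:
        return {line.strip().split("\t")[0] for line in fh if line.strip() and not line.startswith("#")}


def write_cohort(records: list, path) -> None:
    rows = [
        {
            "subject_id": r.subject_id,
            "group": r.group,
            "age": r.age,
            "tnm": r.tnm or "N/A",
            "localization": r.localization or "N/A",
        }
        for r in records
    ]
    pd.DataFrame(rows, columns=["subject_id", "group", "age", "tnm", "localization"]).to_csv(
        path, sep="\t", index=False
    )


def read_cohort(path) -> list:
    from .clinical import records_from_frame

    df = pd.read_csv(path, sep="\t", keep_default_na=False)
    return records_from_frame(df)
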