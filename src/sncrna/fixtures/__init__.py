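"""Packaged fixture tables: verbatim TSV transcriptions of the published
cohort and differential-abundance tables, with pinned checksums.

These are data transcriptions, not computations; ``load_fixture`` verifies
the checksum and the schema before returning a typed DataFrame.
"""

from __future__ import annotations

import hashlib
from importlib import resources

import pandas as pd

from ..core import InputError

_CHECKSUMS = {
    "table1": "3713f1bf51467647e24d9d79eb851a934b3325eb8309f1213ec3269602b2e648",
    "table2": "a298d4d79eecdbb8dd146913ec871d7fd8bc61578a2fc167aab166b16833a539",
    "table3": "41c025c07f42718e1ad7388849f8cfec120431058ffbbccd4c28292ce3e96c9a",
    "table4": "fc953a75f403e69458fc2b72b69a89587cb220fa3c49a04d6e0eddd35b6edbe0",
    "run_summary": "e55e42730a802489862495f75cd1b60e6d993bf69a2cc5af356edd4cf754e4e5",
}

_SCHEMAS = {
    "table1": ["subject_id", "group", "age", "tnm", "localization"],
    "table2": ["id", "status", "coordinates", "cpm", "fc", "pvalue", "fdr"],
    "table3": ["id", "coordinates", "cpm", "fc", "pvalue", "fdr"],
    "table4": ["id", "end", "coordinates", "cpm", "fc", "pvalue", "fdr"],
    "run_summary": ["metric", "value"],
}


class FixtureCorruptionError(RuntimeError):
    pass


def fixture_bytes(name: str) -> bytes:
    if name not in _CHECKSUMS:
        raise InputError(f"unknown fixture {name!r}; available: {sorted(_CHECKSUMS)}")
    data = resources.files(__package__).joinpath(f"{name}.tsv").read_bytes()
    digest = hashlib.sha256(data).hexdigest()
    if digest != _CHECKSUMS[name]:
        raise FixtureCorruptionError(
            f"fixture {name!r} checksum mismatch: {digest} != {_CHECKSUMS[name]}"
        )
    return data


def load_fixture(name: str) -> pd.DataFrame:
    """Load a packaged fixture table after checksum and schema validation."""
    import io

    df = pd.read_csv(io.BytesIO(fixture_bytes(name)), sep="\t", keep_default_na=False,
                     na_values=[])
    expected = _SCHEMAS[name]
    if list(df.columns) != expected:
        raise FixtureCorruptionError(
            f"fixture {name!r} schema mismatch: {list(df.columns)} != {expected}"
        )
    for col in ("cpm", "fc", "pvalue", "fdr"):
        if col in df.columns:
            df[col] = df[col].astype(float)
    if "age" in df.columns:
        df["age"] = df["age"].astype(int)
    if name == "table4" and not set(df["end"]) <= {"5p", "3p"}:
        raise FixtureCorruptionError("table4 end labels must be 5p/3p")
    return df


def run_summary() -> dict:
    df = load_fixture("run_summary")
    return {str(k): float(v) for k, v in zip(df["metric"], df["value"])}
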