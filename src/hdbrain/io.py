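"""Readers and writers for the pipeline's tab-separated file formats.

All tables are TSV with a header row. Files written by this package carry a
sidecar schema comment (a leading ``# columns: ...`` line) naming the columns
in order; readers validate the comment against the actual header when it is
present, so silently re-ordered or truncated tables are caught at load time.

Genesets use the GMT dialect: one set per line,
``name <TAB> description <TAB> member1 <TAB> member2 ...``.
Gene identifiers are opaque strings and are matched exactly; versioned
Ensembl identifiers (``ENSG...​.10``) can optionally be stripped of the
version suffix when joining biotype maps.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .errors import SchemaError

logger = logging.getLogger(__name__)

SCHEMA_PREFIX = "# columns: "


def _read_schema_comment(path: Path) -> list[str] | None:
    with open(path) as fh:
        first = fh.readline()
    if first.startswith(SCHEMA_PREFIX):
        return first[len(SCHEMA_PREFIX):].rstrip("\n").split("\t")
    return None


def _validate_schema(path: Path, columns: list[str]) -> None:
    declared = _read_schema_comment(Path(path))
    if declared is not None and declared != list(columns):
        raise SchemaError(
            f"{path}: schema comment declares columns {declared} "
            f"but table has {list(columns)}"
        )


def write_table(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    """Write a TSV with a leading schema comment line."""
    path = Path(path)
    cols = ([df.index.name or "index"] if index else []) + list(map(str, df.columns))
    with open(path, "w") as fh:
        fh.write(SCHEMA_PREFIX + "\t".join(cols) + "\n")
    df.to_csv(path, sep="\t", mode="a", index=index)


def read_table(path: str | Path, **kwargs) -> pd.DataFrame:
    """Read a TSV written by :func:`write_table` (schema comment optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", **kwargs)
    cols = ([df.index.name] if df.index.name else []) + list(map(str, df.columns))
    if _read_schema_comment(Path(path)) is not None:
        _validate_schema(Path(path), cols)
    return df


def read_counts(path: str | Path) -> pd.DataFrame:
    """Load a gene x sample raw count matrix.

    First column holds gene identifiers, header row holds sample identifiers.
    Cells must be non-negative integers; the offending cell is named on error.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate gene identifier {dup!r}")
    if df.columns.duplicated().any():
        dup = df.columns[df.columns.duplicated()][0]
        raise SchemaError(f"{path}: duplicate sample identifier {dup!r}")
    for col in df.columns:
        vals = df[col]
        numeric = pd.to_numeric(vals, errors="coerce")
        bad = numeric.isna() | (numeric != np.floor(numeric)) | (numeric < 0)
        if bad.any():
            gene = df.index[bad.to_numpy()][0]
            raise SchemaError(
                f"{path}: cell (gene {gene!r}, sample {col!r}) is not a "
                f"non-negative integer: {vals[bad.to_numpy()].iloc[0]!r}"
            )
    return df.astype(np.int64)


def write_counts(counts: pd.DataFrame, path: str | Path) -> None:
    counts = counts.copy()
    counts.index.name = counts.index.name or "gene_id"
    write_table(counts, path, index=True)


def read_sample_table(path: str | Path) -> pd.DataFrame:
    """Load per-sample metadata (condition, age, RIN, case-only clinical columns).

    Missing markers ('unk', 'NA', empty) become NaN in numeric columns.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0,
                     na_values=["unk", "NA", ""])
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise SchemaError(f"{path}: duplicate sample identifier {dup!r}")
    return df


def write_sample_table(samples: pd.DataFrame, path: str | Path) -> None:
    samples = samples.copy()
    samples.index.name = samples.index.name or "sample_id"
    write_table(samples, path, index=True)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Parse a GMT geneset file into ``{set_name: [members...]}``.

    Duplicate members within a set are dropped (order preserved, logged);
    duplicate set names are rejected; lines with fewer than three fields are
    a parse error naming the line.
    """
    sets: dict[str, list[str]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise SchemaError(
                    f"{path}:{lineno}: GMT line has {len(fields)} fields, "
                    "expected name, description, and at least one member"
                )
            name = fields[0]
            if name in sets:
                raise SchemaError(f"{path}:{lineno}: duplicate set name {name!r}")
            members = [m for m in fields[2:] if m]
            if not members:
                logger.warning("%s:%d: set %r has no members, dropped",
                               path, lineno, name)
                continue
            deduped = list(dict.fromkeys(members))
            if len(deduped) < len(members):
                logger.warning("%s:%d: set %r had duplicate members, deduplicated",
                               path, lineno, name)
            sets[name] = deduped
    return sets


def write_gmt(sets: Mapping[str, list[str]], path: str | Path,
              descriptions: Mapping[str, str] | None = None) -> None:
    with open(path, "w") as fh:
        for name, members in sets.items():
            desc = (descriptions or {}).get(name, "na")
            fh.write("\t".join([name, desc, *members]) + "\n")


def read_biotypes(path: str | Path, strip_versions: bool = False) -> dict[str, str]:
    """Load a two-column gene -> biotype map."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise SchemaError(f"{path}: biotype map needs two columns (gene_id, biotype)")
    genes = df.iloc[:, 0].astype(str)
    if strip_versions:
        genes = genes.str.replace(r"\.\d+$", "", regex=True)
    return dict(zip(genes, df.iloc[:, 1].astype(str)))


def read_hierarchy(path: str | Path) -> list[tuple[str, str]]:
    """Load child-TAB-parent term edges (GO-style is_a links)."""
    edges = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise SchemaError(f"{path}:{lineno}: expected child<TAB>parent")
            edges.append((fields[0], fields[1]))
    return edges
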