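"""Readers and writers for the on-disk formats.

All formats are plain text: GMT gene sets, per-source omics TSV (first
column sample id, header row of gene names), per-slide patch tables
(columns ``x``, ``y``, ``f0..f{d-1}``), and outcome TSVs.  Floats are
written with ``%.17g`` so that write/read round-trips are exact at float64.
Readers reject malformed input rather than coercing it.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError
from .omics import GeneSetCollection, OmicsSource
from .wsi import PatchBag

__all__ = [
    "read_gmt", "write_gmt",
    "read_omics", "write_omics",
    "read_patch_table", "write_patch_table",
    "read_outcomes", "write_labels", "write_survival",
    "read_cohort_dir",
]

_FLOAT_FMT = "%.17g"


# ---------------------------------------------------------------- gene sets
def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: tab-separated ``name<TAB>description<TAB>genes...``.

    Duplicate genes within a line are stored once (first occurrence); empty
    lines are skipped; both LF and CRLF line endings are accepted.
    """
    path = Path(path)
    pathways: list[tuple[str, list[str]]] = []
    with path.open("r", newline="") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\r\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}:{lineno}: GMT line needs name, description and >=1 gene"
                )
            name = fields[0]
            genes: list[str] = []
            seen = set()
            for g in fields[2:]:
                if g and g not in seen:
                    genes.append(g)
                    seen.add(g)
            pathways.append((name, genes))
    return GeneSetCollection(pathways=pathways)


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        for name, genes in sets.pathways:
            fh.write("\t".join([name, "synthetic"] + list(genes)) + "\n")


# ------------------------------------------------------------------- omics
def read_omics(path: str | Path, source_name: str) -> OmicsSource:
    """Read a samples x genes TSV (sample ids in the first column)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise FormatError(f"{path}: duplicate sample id {dup!r}")
    values = np.empty(df.shape, dtype=np.float64)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = df[col].astype(np.float64).to_numpy()
        except (TypeError, ValueError) as exc:
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            row = bad.index[0] if len(bad) else "?"
            raise FormatError(
                f"{path}: non-numeric cell at sample {row!r}, gene {col!r}"
            ) from exc
    if np.isnan(values).any():
        i, j = np.argwhere(np.isnan(values))[0]
        raise FormatError(
            f"{path}: missing value at sample {df.index[i]!r}, gene {df.columns[j]!r}"
        )
    return OmicsSource(name=source_name, matrix=values,
                       gene_names=list(df.columns), sample_ids=list(df.index))


def write_omics(source: OmicsSource, path: str | Path) -> None:
    ids = source.sample_ids or [f"S{i:04d}" for i in range(source.matrix.shape[0])]
    with Path(path).open("w") as fh:
        fh.write("sample_id\t" + "\t".join(source.gene_names) + "\n")
        for sid, row in zip(ids, source.matrix):
            fh.write(sid + "\t" + "\t".join(_FLOAT_FMT % v for v in row) + "\n")


# ------------------------------------------------------------ patch tables
def read_patch_table(path: str | Path, slide_id: str | None = None) -> PatchBag:
    """Read a per-slide patch table with columns ``x, y, f0..f{d-1}``."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    cols = list(df.columns)
    if cols[:2] != ["x", "y"]:
        raise FormatError(f"{path}: first two columns must be 'x' and 'y'")
    feat_cols = cols[2:]
    expected = [f"f{i}" for i in range(len(feat_cols))]
    if feat_cols != expected:
        raise FormatError(f"{path}: feature columns must be f0..f{len(feat_cols)-1}")
    try:
        coords = df[["x", "y"]].to_numpy(dtype=np.float64)
        feats = df[feat_cols].to_numpy(dtype=np.float64)
    except (TypeError, ValueError) as exc:
        raise FormatError(f"{path}: non-numeric value in patch table") from exc
    return PatchBag(features=feats, coords=coords, slide_id=slide_id or path.stem)


def write_patch_table(bag: PatchBag, path: str | Path) -> None:
    d = bag.features.shape[1]
    with Path(path).open("w") as fh:
        fh.write("x\ty\t" + "\t".join(f"f{i}" for i in range(d)) + "\n")
        for g, h in zip(bag.coords, bag.features):
            fh.write("\t".join(_FLOAT_FMT % v for v in list(g) + list(h)) + "\n")


# ---------------------------------------------------------------- outcomes
def write_labels(sample_ids, labels, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\tlabel\n")
        for sid, lab in zip(sample_ids, labels):
            fh.write(f"{sid}\t{int(lab)}\n")


def write_survival(sample_ids, times, events, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample_id\ttime\tevent\n")
        for sid, t, e in zip(sample_ids, times, events):
            fh.write(f"{sid}\t{_FLOAT_FMT % t}\t{int(e)}\n")


def read_outcomes(path: str | Path) -> pd.DataFrame:
    """Read an outcome TSV: (sample_id, label) or (sample_id, time, event)."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    cols = list(df.columns)
    if cols == ["sample_id", "label"]:
        pass
    elif cols == ["sample_id", "time", "event"]:
        if (df["time"] <= 0).any():
            raise FormatError(f"{path}: survival times must be positive")
        if not df["event"].isin([0, 1]).all():
            raise FormatError(f"{path}: event indicator must be 0 or 1")
    else:
        raise FormatError(f"{path}: unrecognized outcome columns {cols}")
    if df["sample_id"].duplicated().any():
        raise FormatError(f"{path}: duplicate sample ids")
    return df


# ----------------------------------------------------------- whole cohorts
def read_cohort_dir(directory: str | Path):
    """Load a cohort written by :func:`pathomix.synthetic.write_cohort`.

    Returns ``(patch_bags, sources, gene_sets, outcomes_df, manifest)``.
    """
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    bags = [read_patch_table(directory / rel) for rel in manifest["patch_files"]]
    sources = [
        read_omics(directory / fname, name)
        for name, fname in manifest["omics_files"].items()
    ]
    gene_sets = read_gmt(directory / manifest["gene_sets"])
    outcomes = read_outcomes(directory / manifest["outcomes"])
    order = {sid: i for i, sid in enumerate(b.slide_id for b in bags)}
    if set(outcomes["sample_id"]) != set(order):
        raise ValidationError("outcome sample ids do not match patch files")
    outcomes = outcomes.set_index("sample_id").loc[[b.slide_id for b in bags]].reset_index()
    return bags, sources, gene_sets, outcomes, manifest
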