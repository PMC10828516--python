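"""Readers and writers for the pipeline's on-disk formats.

All coordinates are 0-based half-open internally and in BED; GFF3 input
(1-based closed) is converted at parse time.  Stochastic writers record
the generating seed in a ``#`` header comment.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import EpihaplotypeMap

__all__ = [
    "write_marker_map",
    "read_marker_map",
    "write_state_matrix",
    "read_state_matrix",
    "write_bed",
    "read_bed",
    "read_gff3_genes",
    "write_table",
    "read_table",
]

_GFF3_FIELDS = 9


def _write_with_header(df: pd.DataFrame, path, seed=None, sep=","):
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed={seed}\n")
        df.to_csv(fh, sep=sep, index=False)


def write_marker_map(epihap_map: EpihaplotypeMap, path, seed=None) -> None:
    """Marker map CSV: marker_id, chrom, cM, bp, one MM/UU column per line."""
    out = epihap_map.markers.copy()
    if not epihap_map.genotypes.empty:
        geno = epihap_map.genotypes.T  # markers x lines
        geno.index.name = "marker_id"
        out = out.merge(geno, left_on="marker_id", right_index=True)
    _write_with_header(out, path, seed=seed, sep=",")


def read_marker_map(path) -> EpihaplotypeMap:
    df = pd.read_csv(path, comment="#")
    meta_cols = ["marker_id", "chrom", "cM", "bp"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"marker map missing columns: {missing}")
    line_cols = [c for c in df.columns if c not in meta_cols]
    genotypes = df.set_index("marker_id")[line_cols].T if line_cols else pd.DataFrame()
    if not genotypes.empty:
        bad = ~genotypes.isin(["MM", "UU"]).all(axis=None)
        if bad:
            raise ValueError("epigenotype calls must be MM or UU")
    return EpihaplotypeMap(markers=df[meta_cols].copy(), genotypes=genotypes)


def write_state_matrix(regions: pd.DataFrame, states: pd.DataFrame, path,
                       seed=None) -> None:
    """StateMatrix TSV: region metadata plus one state column per sample."""
    meta = regions[["region_id", "chrom", "start", "end", "context"]]
    out = meta.merge(states, left_on="region_id", right_index=True)
    _write_with_header(out, path, seed=seed, sep="\t")


def read_state_matrix(path) -> tuple:
    """Returns ``(region_meta, states)`` with states indexed by region_id."""
    df = pd.read_csv(path, sep="\t", comment="#")
    meta_cols = ["region_id", "chrom", "start", "end", "context"]
    missing = [c for c in meta_cols if c not in df.columns]
    if missing:
        raise ValueError(f"state matrix missing columns: {missing}")
    if df["region_id"].duplicated().any():
        dup = df.loc[df["region_id"].duplicated(), "region_id"].iloc[0]
        raise ValueError(f"duplicate region_id {dup!r}")
    sample_cols = [c for c in df.columns if c not in meta_cols]
    states = df.set_index("region_id")[sample_cols]
    allowed = np.isin(states.to_numpy(dtype=float), (0.0, 0.5, 1.0)).all()
    if not allowed:
        raise ValueError("state values must be 0, 0.5 or 1")
    return df[meta_cols].copy(), states


def write_bed(intervals: pd.DataFrame, path) -> None:
    """BED (0-based half-open): chrom, start, end [, name]."""
    cols = ["chrom", "start", "end"]
    if "region_id" in intervals.columns:
        cols = cols + ["region_id"]
    intervals[cols].to_csv(path, sep="\t", header=False, index=False)


def read_bed(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "region_id"][: df.shape[1]]
    df.columns = names + list(df.columns[len(names):])
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].index[0]
        raise ValueError(f"BED interval with start >= end at row {bad}")
    return df[names]


def read_gff3_genes(path, feature_types: tuple = ("gene",)) -> pd.DataFrame:
    """Gene intervals from a GFF3 file, converted to 0-based half-open.

    Lines are validated as they are read; a malformed line (wrong field
    count, non-integer coordinates, start > end) raises with its line
    number.  Gene ids come from the ``ID=`` attribute (falling back to
    ``Name=`` or a positional id).
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != _GFF3_FIELDS:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: "
                    f"expected {_GFF3_FIELDS} fields, got {len(fields)}"
                )
            if fields[2] not in feature_types:
                continue
            try:
                start1, end1 = int(fields[3]), int(fields[4])
            except ValueError as exc:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: non-integer coordinates"
                ) from exc
            if start1 > end1:
                raise ValueError(
                    f"{path}: malformed GFF3 line {lineno}: start > end"
                )
            attrs = dict(
                kv.split("=", 1) for kv in fields[8].split(";") if "=" in kv
            )
            gene_id = attrs.get("ID") or attrs.get("Name") or f"gene_line{lineno}"
            rows.append(
                {
                    "gene_id": gene_id,
                    "chrom": fields[0],
                    "start": start1 - 1,  # GFF3 is 1-based closed
                    "end": end1,
                    "strand": fields[6],
                }
            )
    return pd.DataFrame(rows, columns=["gene_id", "chrom", "start", "end", "strand"])


def write_table(df: pd.DataFrame, path, seed=None) -> None:
    """Generic TSV writer with optional seed header."""
    _write_with_header(df, path, seed=seed, sep="\t")


def read_table(path, schema: dict | None = None) -> pd.DataFrame:
    """Generic TSV reader with optional column-type validation.

    ``schema`` maps required column names to dtypes to coerce; a missing
    column raises naming it.
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    if schema:
        for col, dtype in schema.items():
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r} in {path}")
            df[col] = df[col].astype(dtype)
    return df
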