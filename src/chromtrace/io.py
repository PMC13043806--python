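"""Readers and writers for the formats the pipeline touches.

Conventions used everywhere: genomic intervals are 0-based half-open
``[start, end)``; a fragment's two Tn5 insertion sites are ``start`` and
``end - 1`` (endpoints are assumed already Tn5-shifted, 10x style); fragment
files are 5-column TSV (chrom, start, end, barcode, count), optionally
gzipped, sorted by (chrom, start), with ``#`` header lines allowed.
"""

from __future__ import annotations

import gzip
import io as _io
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


@dataclass(frozen=True)
class GenomicInterval:
    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"empty interval {self.chrom}:{self.start}-{self.end}")

    @property
    def width(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def label(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @classmethod
    def from_label(cls, label: str) -> "GenomicInterval":
        chrom, rest = label.rsplit(":", 1)
        start, end = rest.split("-")
        return cls(chrom, int(start), int(end))


@dataclass(frozen=True)
class FragmentRecord:
    chrom: str
    start: int
    end: int
    barcode: str
    count: int = 1


def _open_text(path: str | Path, mode: str = "rt"):
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, mode)
    return open(path, mode)


def read_fragments(
    path: str | Path, barcode_whitelist: set[str] | None = None
) -> Iterator[FragmentRecord]:
    """Stream fragment records from a (gzipped) 5-column TSV.

    Malformed lines raise a ``ValueError`` naming the offending line number.
    """
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith("#") or not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 5:
                raise ValueError(
                    f"{path}: line {lineno}: expected 5 columns, got {len(parts)}"
                )
            chrom, start_s, end_s, barcode, count_s = parts
            try:
                start, end, count = int(start_s), int(end_s), int(count_s)
            except ValueError as exc:
                raise ValueError(f"{path}: line {lineno}: non-integer field") from exc
            if start < 0 or end <= start or count <= 0:
                raise ValueError(
                    f"{path}: line {lineno}: invalid fragment "
                    f"({chrom}:{start}-{end}, count={count})"
                )
            if barcode_whitelist is not None and barcode not in barcode_whitelist:
                continue
            yield FragmentRecord(chrom, start, end, barcode, count)


_FRAG_COLUMNS = ["chrom", "start", "end", "barcode", "count"]


def load_fragments_df(
    path: str | Path, barcode_whitelist: set[str] | None = None
) -> pd.DataFrame:
    """Load a fragment file into a DataFrame (columnar fast path)."""
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=_FRAG_COLUMNS,
        dtype={"chrom": str, "start": np.int64, "end": np.int64,
               "barcode": str, "count": np.int64},
    )
    if (df["end"] <= df["start"]).any() or (df["start"] < 0).any():
        bad = int(np.argmax((df["end"] <= df["start"]) | (df["start"] < 0)))
        raise ValueError(f"{path}: invalid interval at record {bad}")
    if barcode_whitelist is not None:
        df = df[df["barcode"].isin(barcode_whitelist)].reset_index(drop=True)
    return df


def write_fragments_df(df: pd.DataFrame, path: str | Path) -> None:
    """Write fragments sorted by (chrom, start) as (gzipped) TSV."""
    df = df.sort_values(["chrom", "start"], kind="stable")
    df.to_csv(path, sep="\t", header=False, index=False, columns=_FRAG_COLUMNS)


@dataclass
class FeatureMatrix:
    """Sparse cells x features count matrix.

    ``flavor`` is one of ``tile``, ``peak``, ``gene_score``.  ``depth`` caches
    the per-cell total fragment count (not the matrix row sum — peak-matrix
    entries are capped, gene scores are weighted).
    """

    counts: sp.csr_matrix
    barcodes: list[str]
    features: list[str]
    flavor: str
    depth: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        if self.counts.shape != (len(self.barcodes), len(self.features)):
            raise ValueError(
                f"shape {self.counts.shape} does not match "
                f"{len(self.barcodes)} barcodes x {len(self.features)} features"
            )
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("duplicate barcodes")
        if len(set(self.features)) != len(self.features):
            raise ValueError("duplicate features")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def feature_intervals(self) -> list[GenomicInterval]:
        return [GenomicInterval.from_label(f) for f in self.features]

    def subset_cells(self, keep: Iterable[str]) -> "FeatureMatrix":
        keep = list(keep)
        index = {b: i for i, b in enumerate(self.barcodes)}
        rows = np.array([index[b] for b in keep], dtype=int)
        depth = self.depth[rows] if self.depth is not None else None
        return FeatureMatrix(self.counts[rows], keep, list(self.features),
                             self.flavor, depth)


def write_matrix(matrix: FeatureMatrix, out_dir: str | Path) -> None:
    """MatrixMarket triplet + TSV sidecars (barcodes, features, flavor/depth)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(str(out / "matrix.mtx"), sp.coo_matrix(matrix.counts))
    pd.Series(matrix.barcodes, name="barcode").to_csv(
        out / "barcodes.tsv", sep="\t", index=False)
    pd.Series(matrix.features, name="feature").to_csv(
        out / "features.tsv", sep="\t", index=False)
    meta = pd.DataFrame({"flavor": [matrix.flavor]})
    meta.to_csv(out / "flavor.tsv", sep="\t", index=False)
    if matrix.depth is not None:
        pd.Series(matrix.depth, name="depth").to_csv(
            out / "depth.tsv", sep="\t", index=False)


def read_matrix(in_dir: str | Path) -> FeatureMatrix:
    in_dir = Path(in_dir)
    counts = sp.csr_matrix(scipy.io.mmread(str(in_dir / "matrix.mtx")))
    barcodes = pd.read_csv(in_dir / "barcodes.tsv", sep="\t")["barcode"].astype(str)
    features = pd.read_csv(in_dir / "features.tsv", sep="\t")["feature"].astype(str)
    if counts.shape != (len(barcodes), len(features)):
        raise ValueError(
            f"{in_dir}: MTX shape {counts.shape} does not match sidecars "
            f"({len(barcodes)} x {len(features)})"
        )
    flavor = pd.read_csv(in_dir / "flavor.tsv", sep="\t")["flavor"].iloc[0]
    depth = None
    if (in_dir / "depth.tsv").exists():
        depth = pd.read_csv(in_dir / "depth.tsv", sep="\t")["depth"].to_numpy()
    return FeatureMatrix(counts, list(barcodes), list(features), flavor, depth)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read a BED-like TSV; first three columns chrom/start/end, extras kept."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    names = ["chrom", "start", "end"] + [f"col{i}" for i in range(3, df.shape[1])]
    df.columns = names[: df.shape[1]]
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def read_genes_tsv(path: str | Path) -> pd.DataFrame:
    """Gene table: name, chrom, start, end, strand (body 0-based half-open)."""
    df = pd.read_csv(path, sep="\t")
    required = {"name", "chrom", "start", "end", "strand"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: gene TSV needs columns {sorted(required)}")
    return df
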