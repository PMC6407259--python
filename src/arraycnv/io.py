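"""Readers and writers for the tabular and interval formats the pipeline touches.

Coordinate convention
---------------------
All in-memory coordinates are **1-based inclusive** and interval length is
``end - start + 1``.  The only serialization that differs is BED, which is
0-based half-open; the shift happens exactly once, inside :func:`write_bed`
and :func:`read_intervals`.  Missing signal values are written as ``NA`` and
held as NaN in memory.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "SignalMatrix",
    "GenomicInterval",
    "GeneModel",
    "QtlRecord",
    "natural_chrom_key",
    "read_signal_matrix",
    "read_intervals",
    "read_genes",
    "read_qtls",
    "read_trait_table",
    "write_trait_table",
    "write_bed",
    "write_results_tsv",
    "read_results_tsv",
]

_NUM_RE = re.compile(r"(\d+)")


def natural_chrom_key(name: str) -> tuple:
    """Sort key placing chr2 before chr10 and autosomes before chrX."""
    parts = _NUM_RE.split(str(name))
    return tuple(int(p) if p.isdigit() else p for p in parts)


# ---------------------------------------------------------------------------
# interval records
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomicInterval:
    """A named 1-based inclusive interval."""

    name: str
    chrom: str
    start_bp: int
    end_bp: int
    strand: str = "."

    def __post_init__(self):
        if self.start_bp < 1 or self.end_bp < self.start_bp:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start_bp}-{self.end_bp}"
            )

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1


@dataclass(frozen=True)
class GeneModel(GenomicInterval):
    """A gene body; ``name`` is the gene symbol."""

    @property
    def symbol(self) -> str:
        return self.name


@dataclass(frozen=True)
class QtlRecord(GenomicInterval):
    """A QTL confidence interval; ``name`` is the trait label."""

    @property
    def trait(self) -> str:
        return self.name


# ---------------------------------------------------------------------------
# signal matrix
# ---------------------------------------------------------------------------

@dataclass
class SignalMatrix:
    """Probe-by-sample log2-ratio matrix with genomic coordinates.

    Parameters
    ----------
    probes
        DataFrame with columns ``probe_id``, ``chrom``, ``pos`` (1-based bp),
        sorted by (chrom, pos) in natural chromosome order.
    samples
        Ordered sample identifiers, one per value column.
    values
        ``(n_probes, n_samples)`` float array of log2 ratios; NaN = missing.
    """

    probes: pd.DataFrame
    samples: list[str] = field(default_factory=list)
    values: np.ndarray = field(default_factory=lambda: np.empty((0, 0)))

    def __post_init__(self):
        self.probes = self.probes.reset_index(drop=True)
        self.samples = [str(s) for s in self.samples]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    # -- invariants ---------------------------------------------------------
    def validate(self) -> None:
        req = {"probe_id", "chrom", "pos"}
        if not req.issubset(self.probes.columns):
            raise ValueError(f"probe table must have columns {sorted(req)}")
        if self.values.shape != (len(self.probes), len(self.samples)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.probes)} probes x {len(self.samples)} samples"
            )
        dup = self.probes.duplicated(subset=["chrom", "pos"])
        if dup.any():
            row = self.probes[dup].iloc[0]
            raise ValueError(f"duplicate probe at {row['chrom']}:{row['pos']}")
        if not self._is_sorted():
            raise ValueError("probes must be sorted by (chrom, pos)")

    def _is_sorted(self) -> bool:
        keys = [natural_chrom_key(c) for c in self.probes["chrom"]]
        pos = self.probes["pos"].to_numpy()
        for i in range(1, len(keys)):
            if keys[i] < keys[i - 1]:
                return False
            if keys[i] == keys[i - 1] and pos[i] <= pos[i - 1]:
                return False
        return True

    # -- accessors ----------------------------------------------------------
    @property
    def n_probes(self) -> int:
        return len(self.probes)

    @property
    def chromosomes(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.probes["chrom"]:
            seen.setdefault(str(c))
        return list(seen)

    def chrom_index(self, chrom: str) -> np.ndarray:
        """Positional indices of probes on ``chrom`` (in matrix order)."""
        return np.flatnonzero((self.probes["chrom"] == chrom).to_numpy())

    def sample_column(self, sample_id: str) -> np.ndarray:
        return self.values[:, self.samples.index(str(sample_id))]

    def to_frame(self) -> pd.DataFrame:
        out = self.probes[["probe_id", "chrom", "pos"]].copy()
        for j, s in enumerate(self.samples):
            out[s] = self.values[:, j]
        return out

    # -- io -----------------------------------------------------------------
    def write(self, path: str | Path, header_lines: Sequence[str] = ()) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.to_frame().to_csv(fh, sep="\t", index=False, na_rep="NA")

    @classmethod
    def read(cls, path: str | Path) -> "SignalMatrix":
        return read_signal_matrix(path)


def read_signal_matrix(path: str | Path) -> SignalMatrix:
    """Read a signal TSV (probe_id, chrom, pos, one column per sample).

    Duplicate (chrom, pos) probes are rejected; unsorted input is sorted with
    a warning.  Malformed numeric fields raise with the offending line.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str},
                         float_precision="round_trip")
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed signal matrix: {exc}") from exc
    for col in ("probe_id", "chrom", "pos"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column '{col}'")
    sample_cols = [c for c in df.columns if c not in ("probe_id", "chrom", "pos")]
    for col in sample_cols:
        try:
            df[col] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError) as exc:
            bad = df[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
            line = int(bad.index[0]) + 2 if len(bad) else "?"
            raise ValueError(
                f"{path}: malformed value in column '{col}' near line {line}"
            ) from exc
    keys = df["chrom"].map(natural_chrom_key)
    order = sorted(range(len(df)), key=lambda i: (keys.iloc[i], df["pos"].iloc[i]))
    if order != list(range(len(df))):
        warnings.warn(f"{path}: probes were not sorted; sorting", stacklevel=2)
        df = df.iloc[order].reset_index(drop=True)
    probes = df[["probe_id", "chrom", "pos"]].copy()
    probes["pos"] = probes["pos"].astype(int)
    values = df[sample_cols].to_numpy(dtype=float)
    return SignalMatrix(probes=probes, samples=sample_cols, values=values)


# ---------------------------------------------------------------------------
# intervals
# ---------------------------------------------------------------------------

def _parse_gff3_name(attrs: str) -> str:
    for key in ("Name=", "ID=", "gene_id="):
        for fld in attrs.split(";"):
            fld = fld.strip()
            if fld.startswith(key):
                return fld[len(key):].strip('"')
    return attrs.strip() or "."


def read_intervals(path: str | Path, dialect: str) -> list[GenomicInterval]:
    """Read intervals from ``bed`` (0-based half-open), ``gff3`` or ``tsv1``
    (both 1-based inclusive), normalized to internal 1-based inclusive."""
    path = Path(path)
    out: list[GenomicInterval] = []
    if dialect == "bed":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                if len(f) < 3:
                    raise ValueError(f"{path}:{ln}: BED line has <3 fields")
                chrom, start0, end = f[0], int(f[1]), int(f[2])
                if start0 < 0 or end <= start0:
                    raise ValueError(f"{path}:{ln}: invalid BED coordinates")
                name = f[3] if len(f) > 3 else "."
                strand = f[5] if len(f) > 5 else "."
                out.append(GenomicInterval(name, chrom, start0 + 1, end, strand))
    elif dialect == "gff3":
        with open(path) as fh:
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                f = line.split("\t")
                if len(f) < 9:
                    raise ValueError(f"{path}:{ln}: GFF3 line has <9 fields")
                chrom, start, end = f[0], int(f[3]), int(f[4])
                if start < 1 or end < start:
                    raise ValueError(f"{path}:{ln}: invalid GFF3 coordinates")
                out.append(
                    GenomicInterval(_parse_gff3_name(f[8]), chrom, start, end, f[6])
                )
    elif dialect == "tsv1":
        df = pd.read_csv(path, sep="\t", comment="#", dtype={"chrom": str})
        name_col = next(
            (c for c in ("name", "symbol", "trait") if c in df.columns), None
        )
        if name_col is None or not {"chrom", "start", "end"}.issubset(df.columns):
            raise ValueError(
                f"{path}: tsv1 needs columns chrom,start,end and one of name/symbol/trait"
            )
        for i, row in df.iterrows():
            start, end = int(row["start"]), int(row["end"])
            if start < 1 or end < start:
                raise ValueError(f"{path}: line {i + 2}: invalid coordinates")
            strand = str(row["strand"]) if "strand" in df.columns else "."
            out.append(
                GenomicInterval(str(row[name_col]), str(row["chrom"]), start, end, strand)
            )
    else:
        raise ValueError(f"unknown dialect {dialect!r} (use bed, gff3 or tsv1)")
    return out


def read_genes(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    return [
        GeneModel(iv.name, iv.chrom, iv.start_bp, iv.end_bp, iv.strand)
        for iv in read_intervals(path, dialect)
    ]


def read_qtls(path: str | Path, dialect: str = "tsv1") -> list[QtlRecord]:
    return [
        QtlRecord(iv.name, iv.chrom, iv.start_bp, iv.end_bp, iv.strand)
        for iv in read_intervals(path, dialect)
    ]


def write_bed(records: Iterable, path: str | Path,
              header_lines: Sequence[str] = ()) -> None:
    """Write records carrying ``chrom``/``start_bp``/``end_bp`` as BED
    (0-based half-open).  The name field comes from ``bed_name()`` if the
    record defines it, else ``name``, else '.'."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        for rec in records:
            if hasattr(rec, "bed_name"):
                name = rec.bed_name()
            else:
                name = getattr(rec, "name", ".")
            fh.write(f"{rec.chrom}\t{rec.start_bp - 1}\t{rec.end_bp}\t{name}\n")


def write_results_tsv(df: pd.DataFrame, path: str | Path,
                      header_lines: Sequence[str] = ()) -> None:
    """Write a result table as TSV with stable column order; ``NA`` marks
    missing.  An empty table still gets its header row."""
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def read_results_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#",
                       float_precision="round_trip")


# ---------------------------------------------------------------------------
# trait tables
# ---------------------------------------------------------------------------

def read_trait_table(path: str | Path) -> pd.DataFrame:
    """Read a long-format trait table (sample_id, trait, pta_value[, reliability]).

    (sample, trait) pairs must be unique; reliabilities, when present, must
    lie in [0, 1].
    """
    df = pd.read_csv(path, sep="\t", comment="#")
    req = {"sample_id", "trait", "pta_value"}
    if not req.issubset(df.columns):
        raise ValueError(f"{path}: trait table needs columns {sorted(req)}")
    if df.duplicated(subset=["sample_id", "trait"]).any():
        raise ValueError(f"{path}: duplicate (sample_id, trait) pair")
    if "reliability" in df.columns:
        rel = df["reliability"].dropna()
        if ((rel < 0) | (rel > 1)).any():
            raise ValueError(f"{path}: reliability outside [0, 1]")
    df["sample_id"] = df["sample_id"].astype(str)
    return df


def write_trait_table(df: pd.DataFrame, path: str | Path,
                      header_lines: Sequence[str] = ()) -> None:
    write_results_tsv(df, path, header_lines)


def traits_to_wide(df: pd.DataFrame) -> pd.DataFrame:
    """Long trait table -> sample × trait matrix of PTA values."""
    return df.pivot(index="sample_id", columns="trait", values="pta_value")


def traits_to_long(wide: pd.DataFrame) -> pd.DataFrame:
    long = wide.stack().rename("pta_value").reset_index()
    long.columns = ["sample_id", "trait", "pta_value"]
    return long
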