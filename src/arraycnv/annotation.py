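"""Interval annotation of CNVRs against genes, QTLs and external CNVR sets.

All coordinates are 1-based inclusive.  The rules implemented are the
conservative conventions of CNV surveys in livestock:

* gene overlap — ≥1 bp shared with the gene body expanded by a flank
  (3 kb genome-wide; 5 kb when reporting significant CNVRs); CNVRs with no
  overlapping gene get their nearest gene and edge-to-edge distance;
* QTL support — QTL intervals longer than 30 Mb are discarded, then a CNVR
  counts as supported when the union of retained QTLs covers at least 50%
  of its length;
* set comparison — a region is supported by an external CNVR set when the
  set's union covers at least a configurable fraction (default 50%) of the
  region's length.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

__all__ = [
    "AnnotationConfig",
    "OverlapRecord",
    "interval_overlap_bp",
    "overlap_genes",
    "overlap_qtls",
    "compare_cnvr_sets",
    "union_coverage_bp",
]


@dataclass(frozen=True)
class AnnotationConfig:
    gene_flank_bp: int = 3_000
    significant_gene_flank_bp: int = 5_000
    qtl_max_ci_bp: int = 30_000_000
    qtl_min_coverage: float = 0.5
    set_compare_min_fraction: float = 0.5

    def __post_init__(self):
        if self.gene_flank_bp < 0 or self.significant_gene_flank_bp < 0:
            raise ValueError("flanks must be >= 0")
        for frac in (self.qtl_min_coverage, self.set_compare_min_fraction):
            if not 0 < frac <= 1:
                raise ValueError("coverage fractions must be in (0, 1]")


@dataclass(frozen=True)
class OverlapRecord:
    cnvr_id: str
    feature_id: str
    overlap_bp: int
    fraction_of_cnvr: float
    relation: str  # "overlapping" | "nearest"
    distance_bp: int = 0

    def __post_init__(self):
        if self.relation == "overlapping" and self.overlap_bp < 1:
            raise ValueError("overlapping record needs overlap_bp >= 1")


def _coords(rec) -> tuple[str, int, int]:
    return str(rec.chrom), int(rec.start_bp), int(rec.end_bp)


def _length(rec) -> int:
    return int(rec.end_bp) - int(rec.start_bp) + 1


def _feature_name(rec) -> str:
    for attr in ("symbol", "trait", "name", "cnvr_id"):
        v = getattr(rec, attr, None)
        if v is not None:
            return str(v)
    return "."


def interval_overlap_bp(a, b) -> int:
    """Shared bases between two 1-based inclusive intervals; 0 across
    chromosomes (by contract, not an error)."""
    ca, sa, ea = _coords(a)
    cb, sb, eb = _coords(b)
    if ca != cb:
        return 0
    return max(0, min(ea, eb) - max(sa, sb) + 1)


# ---------------------------------------------------------------------------
# genes
# ---------------------------------------------------------------------------

def overlap_genes(cnvrs: Sequence, genes: Sequence,
                  flank_bp: int = 3_000) -> list[OverlapRecord]:
    """Gene-content annotation with flank expansion and nearest-gene fallback.

    A record per (CNVR, gene) pair sharing ≥1 bp after expanding the gene
    by ``flank_bp`` up- and downstream (clipped at 1).  A CNVR with no
    overlapping gene on its chromosome gets one 'nearest' record with the
    edge-to-edge gap in bp (raw gene body, not flanked); distance ties break
    toward the lexicographically smaller symbol.
    """
    records: list[OverlapRecord] = []
    for cnvr in cnvrs:
        cid = _feature_name(cnvr)
        c_chrom, c_start, c_end = _coords(cnvr)
        c_len = _length(cnvr)
        hits = []
        for gene in genes:
            g_chrom, g_start, g_end = _coords(gene)
            if g_chrom != c_chrom:
                continue
            ov = max(0, min(c_end, g_end + flank_bp)
                     - max(c_start, max(1, g_start - flank_bp)) + 1)
            if ov >= 1:
                hits.append(OverlapRecord(cid, _feature_name(gene), int(ov),
                                          ov / c_len, "overlapping", 0))
        if hits:
            records.extend(sorted(hits, key=lambda r: r.feature_id))
            continue
        best = None
        for gene in genes:
            g_chrom, g_start, g_end = _coords(gene)
            if g_chrom != c_chrom:
                continue
            if g_end < c_start:
                dist = c_start - g_end - 1
            elif g_start > c_end:
                dist = g_start - c_end - 1
            else:
                dist = 0
            key = (dist, _feature_name(gene))
            if best is None or key < best[0]:
                best = (key, gene)
        if best is not None:
            dist, _ = best[0]
            records.append(OverlapRecord(cid, _feature_name(best[1]), 0, 0.0,
                                         "nearest", int(dist)))
    return records


# ---------------------------------------------------------------------------
# QTLs
# ---------------------------------------------------------------------------

def union_coverage_bp(region, features: Sequence) -> int:
    """Bases of ``region`` covered by the union of ``features`` (same chrom)."""
    chrom, start, end = _coords(region)
    spans = []
    for f in features:
        f_chrom, f_start, f_end = _coords(f)
        if f_chrom != chrom:
            continue
        s, e = max(start, f_start), min(end, f_end)
        if s <= e:
            spans.append((s, e))
    if not spans:
        return 0
    spans.sort()
    covered, cur_s, cur_e = 0, *spans[0]
    for s, e in spans[1:]:
        if s <= cur_e + 1:
            cur_e = max(cur_e, e)
        else:
            covered += cur_e - cur_s + 1
            cur_s, cur_e = s, e
    covered += cur_e - cur_s + 1
    return covered


def overlap_qtls(regions: Sequence, qtls: Sequence,
                 config: AnnotationConfig | None = None) -> list[OverlapRecord]:
    """QTL support under the 30 Mb confidence-interval filter and the 50%
    union-coverage rule.

    QTLs longer than ``qtl_max_ci_bp`` are discarded first.  For each region
    whose union coverage by retained QTLs reaches ``qtl_min_coverage`` of
    its length, one record is emitted per contributing QTL (≥1 bp shared).
    Regions below the coverage threshold produce no records.
    """
    config = config or AnnotationConfig()
    retained = [q for q in qtls if _length(q) <= config.qtl_max_ci_bp]
    records: list[OverlapRecord] = []
    for region in regions:
        r_len = _length(region)
        covered = union_coverage_bp(region, retained)
        if covered < config.qtl_min_coverage * r_len:
            continue
        rid = _feature_name(region)
        hits = []
        for q in retained:
            ov = interval_overlap_bp(region, q)
            if ov >= 1:
                hits.append(OverlapRecord(rid, _feature_name(q), int(ov),
                                          ov / r_len, "overlapping", 0))
        records.extend(sorted(hits, key=lambda r: (r.feature_id, -r.overlap_bp)))
    return records


# ---------------------------------------------------------------------------
# external CNVR set comparison
# ---------------------------------------------------------------------------

def compare_cnvr_sets(set_a: Sequence, set_b: Sequence,
                      min_fraction: float = 0.5
                      ) -> tuple[pd.DataFrame, dict]:
    """Support of each region in ``set_a`` by the union of ``set_b``.

    A region is supported when set_b's union covers ≥ ``min_fraction`` of
    its length.  Returns a per-region table (region id, length, covered bp,
    fraction, supported) and a summary with the supported count/bp and
    their fractions of set_a.
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    rows = []
    for region in set_a:
        r_len = _length(region)
        covered = union_coverage_bp(region, set_b)
        frac = covered / r_len
        rows.append({
            "region_id": _feature_name(region),
            "chrom": _coords(region)[0],
            "start_bp": _coords(region)[1],
            "end_bp": _coords(region)[2],
            "length_bp": r_len,
            "covered_bp": covered,
            "covered_fraction": frac,
            "supported": frac >= min_fraction,
        })
    table = pd.DataFrame(rows, columns=[
        "region_id", "chrom", "start_bp", "end_bp", "length_bp",
        "covered_bp", "covered_fraction", "supported",
    ])
    n = len(table)
    total_bp = int(table["length_bp"].sum()) if n else 0
    supported = table[table["supported"]] if n else table
    summary = {
        "n_regions": n,
        "n_supported": int(len(supported)),
        "count_fraction": float(len(supported) / n) if n else 0.0,
        "supported_bp": int(supported["length_bp"].sum()) if n else 0,
        "bp_fraction": (float(supported["length_bp"].sum()) / total_bp
                        if total_bp else 0.0),
    }
    return table, summary
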