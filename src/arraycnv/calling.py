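"""CNV calling from segmentations and cross-sample CNVR construction.

Calling follows the conservative "0.5_5" rule: a segment becomes a call
when its mean log2 ratio is at least 0.5 in absolute value across at least
5 consecutive probes.  Calls are then length-filtered with strict bounds
(1 kb < length < 5 Mb) to drop likely artifacts, and calls from all samples
are aggregated into CNV regions (CNVRs): connected components under ≥1 bp
overlap, classified loss / gain / both.  Bookended calls (end+1 == start)
do not merge, and sub-threshold gaps between qualifying segments are not
bridged.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd

from .io import natural_chrom_key
from .segmentation import Segment

__all__ = [
    "CallingConfig",
    "CnvCall",
    "CnvRegion",
    "call_cnvs",
    "call_cnvs_from_table",
    "filter_cnvs",
    "merge_to_cnvrs",
    "summarize_cnvs",
    "is_placed_chromosome",
]


@dataclass(frozen=True)
class CallingConfig:
    """Thresholds of the 0.5_5 rule and the strict length filter."""

    log2_threshold: float = 0.5
    min_probes: int = 5
    min_length_bp: int = 1_000       # exclusive lower bound
    max_length_bp: int = 5_000_000   # exclusive upper bound

    def __post_init__(self):
        if self.log2_threshold <= 0:
            raise ValueError("log2_threshold must be > 0")
        if self.min_probes < 1:
            raise ValueError("min_probes must be >= 1")
        if self.min_length_bp >= self.max_length_bp:
            raise ValueError("min_length_bp must be < max_length_bp")


@dataclass(frozen=True)
class CnvCall:
    """One contiguous gain/loss event in one sample (1-based inclusive)."""

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    state: str  # "gain" | "loss"
    mean_log2: float
    n_probes: int

    def __post_init__(self):
        if self.state not in ("gain", "loss"):
            raise ValueError(f"state must be gain or loss, got {self.state!r}")
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def bed_name(self) -> str:
        return f"{self.sample_id}:{self.state}"


@dataclass(frozen=True)
class CnvRegion:
    """Union of overlapping calls across samples."""

    cnvr_id: str
    chrom: str
    start_bp: int
    end_bp: int
    state: str  # "loss" | "gain" | "both"
    member_calls: tuple[CnvCall, ...] = field(default_factory=tuple, repr=False)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    @property
    def n_samples(self) -> int:
        return len({c.sample_id for c in self.member_calls})

    def bed_name(self) -> str:
        return f"{self.cnvr_id}:{self.state}"


def is_placed_chromosome(chrom: str) -> bool:
    """False for unplaced/unlocalized sequence (chrUn-like, *_random)."""
    c = str(chrom)
    return not (c.lower().startswith("chrun") or "_" in c or c.lower() == "un")


# ---------------------------------------------------------------------------
# calling
# ---------------------------------------------------------------------------

def call_cnvs(segments: Sequence[Segment], config: CallingConfig,
              sample_id: str) -> list[CnvCall]:
    """Apply the 0.5_5 rule to one sample's segments.

    A segment qualifies when |mean_log2| ≥ threshold and n_probes ≥
    min_probes; adjacent qualifying segments of the same state (contiguous
    in probe index, same chromosome) are merged into a single call with a
    probe-count-weighted mean.
    """
    t = config.log2_threshold
    qualifying = [
        s for s in segments
        if abs(s.mean_log2) >= t and s.n_probes >= config.min_probes
    ]
    calls: list[CnvCall] = []
    run: list[Segment] = []

    def flush():
        if not run:
            return
        n = sum(s.n_probes for s in run)
        mean = sum(s.mean_log2 * s.n_probes for s in run) / n
        calls.append(CnvCall(
            sample_id=sample_id,
            chrom=run[0].chrom,
            start_bp=run[0].start_bp,
            end_bp=run[-1].end_bp,
            state="gain" if mean >= 0 else "loss",
            mean_log2=float(mean),
            n_probes=n,
        ))
        run.clear()

    for seg in qualifying:
        state = "gain" if seg.mean_log2 >= t else "loss"
        if run:
            prev = run[-1]
            prev_state = "gain" if prev.mean_log2 >= t else "loss"
            contiguous = (
                seg.chrom == prev.chrom
                and seg.first_probe_index == prev.last_probe_index + 1
                and state == prev_state
            )
            if not contiguous:
                flush()
        run.append(seg)
    flush()
    return calls


def call_cnvs_from_table(segments: pd.DataFrame,
                         config: CallingConfig) -> list[CnvCall]:
    """Call CNVs for every sample in a tidy segment table
    (as produced by :func:`arraycnv.segmentation.segment_matrix`)."""
    calls: list[CnvCall] = []
    for sample, grp in segments.groupby("sample", sort=True):
        segs = [
            Segment(r.chrom, int(r.first_probe_index), int(r.last_probe_index),
                    int(r.start_bp), int(r.end_bp), float(r.mean_log2),
                    int(r.n_probes))
            for r in grp.itertuples()
        ]
        calls.extend(call_cnvs(segs, config, str(sample)))
    return calls


def filter_cnvs(calls: Iterable[CnvCall], config: CallingConfig) -> list[CnvCall]:
    """Strict length filter: retain 1,000 < length_bp < 5,000,000 only
    (boundary values excluded)."""
    return [
        c for c in calls
        if config.min_length_bp < c.length_bp < config.max_length_bp
    ]


# ---------------------------------------------------------------------------
# CNVR construction
# ---------------------------------------------------------------------------

def merge_to_cnvrs(calls: Sequence[CnvCall]) -> list[CnvRegion]:
    """Aggregate calls across samples into CNVRs.

    Connected components under ≥1 bp overlap (1-based inclusive: next.start
    ≤ current hull end) become regions; the span is the union hull of the
    members, the state is 'both' when members include a gain and a loss.
    IDs are assigned in genomic order (natural chromosome order, then
    start).
    """
    ordered = sorted(
        calls, key=lambda c: (natural_chrom_key(c.chrom), c.start_bp, c.end_bp,
                              c.sample_id)
    )
    groups: list[list[CnvCall]] = []
    cur: list[CnvCall] = []
    cur_end = -1
    for call in ordered:
        if cur and call.chrom == cur[0].chrom and call.start_bp <= cur_end:
            cur.append(call)
            cur_end = max(cur_end, call.end_bp)
        else:
            if cur:
                groups.append(cur)
            cur = [call]
            cur_end = call.end_bp
    if cur:
        groups.append(cur)

    width = max(3, len(str(len(groups))))
    regions = []
    for i, grp in enumerate(groups, 1):
        states = {c.state for c in grp}
        state = "both" if states == {"gain", "loss"} else states.pop()
        regions.append(CnvRegion(
            cnvr_id=f"CNVR{i:0{width}d}",
            chrom=grp[0].chrom,
            start_bp=min(c.start_bp for c in grp),
            end_bp=max(c.end_bp for c in grp),
            state=state,
            member_calls=tuple(grp),
        ))
    return regions


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------

def summarize_cnvs(calls: Sequence[CnvCall], cnvrs: Sequence[CnvRegion],
                   chromosome_lengths: dict[str, int] | None = None) -> dict:
    """Cohort summary: per-chromosome call counts and mean lengths,
    per-sample mean event count, CNVR counts by state, total CNVR bp and
    genome fraction over placed chromosomes."""
    per_chrom: dict[str, dict] = {}
    for c in calls:
        d = per_chrom.setdefault(c.chrom, {"n_cnvs": 0, "total_bp": 0})
        d["n_cnvs"] += 1
        d["total_bp"] += c.length_bp
    for d in per_chrom.values():
        d["mean_length_bp"] = d["total_bp"] / d["n_cnvs"] if d["n_cnvs"] else 0.0

    samples = {c.sample_id for c in calls}
    mean_events = len(calls) / len(samples) if samples else 0.0

    state_counts = {"loss": 0, "gain": 0, "both": 0}
    for r in cnvrs:
        state_counts[r.state] += 1
    total_cnvr_bp = int(sum(r.length_bp for r in cnvrs))

    genome_fraction = None
    if chromosome_lengths:
        placed = sum(
            L for name, L in chromosome_lengths.items()
            if is_placed_chromosome(name)
        )
        if placed > 0:
            placed_cnvr_bp = sum(
                r.length_bp for r in cnvrs if is_placed_chromosome(r.chrom)
            )
            genome_fraction = placed_cnvr_bp / placed

    return {
        "n_cnvs": len(calls),
        "n_samples_with_calls": len(samples),
        "mean_events_per_sample": mean_events,
        "per_chromosome": per_chrom,
        "n_cnvrs": len(cnvrs),
        "cnvr_state_counts": state_counts,
        "total_cnvr_bp": total_cnvr_bp,
        "genome_cnvr_fraction": genome_fraction,
    }


def calls_to_frame(calls: Sequence[CnvCall]) -> pd.DataFrame:
    return pd.DataFrame([
        {"sample": c.sample_id, "chrom": c.chrom, "start_bp": c.start_bp,
         "end_bp": c.end_bp, "state": c.state, "mean_log2": c.mean_log2,
         "n_probes": c.n_probes, "length_bp": c.length_bp}
        for c in calls
    ], columns=["sample", "chrom", "start_bp", "end_bp", "state",
                "mean_log2", "n_probes", "length_bp"])


def cnvrs_to_frame(cnvrs: Sequence[CnvRegion]) -> pd.DataFrame:
    return pd.DataFrame([
        {"cnvr_id": r.cnvr_id, "chrom": r.chrom, "start_bp": r.start_bp,
         "end_bp": r.end_bp, "state": r.state, "n_samples": r.n_samples,
         "n_calls": len(r.member_calls), "length_bp": r.length_bp}
        for r in cnvrs
    ], columns=["cnvr_id", "chrom", "start_bp", "end_bp", "state",
                "n_samples", "n_calls", "length_bp"])
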