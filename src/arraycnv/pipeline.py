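"""End-to-end orchestration: simulate → segment → call/merge → associate →
annotate, with one YAML-serializable configuration, a single master seed,
and a machine-readable run report.

Each stage is a plain function reading its upstream files from the run
directory and writing TSV/BED outputs with provenance headers (package
version, config hash, seed).  Re-running a stage with unchanged inputs and
seed reproduces its outputs byte-for-byte.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotation import AnnotationConfig, compare_cnvr_sets, overlap_genes, overlap_qtls
from .association import run_association
from .calling import (CallingConfig, CnvCall, CnvRegion, call_cnvs_from_table,
                      calls_to_frame, cnvrs_to_frame, filter_cnvs,
                      merge_to_cnvrs, summarize_cnvs)
from .io import (SignalMatrix, read_genes, read_qtls, read_signal_matrix,
                 read_trait_table, traits_to_long, traits_to_wide, write_bed,
                 write_results_tsv)
from .segmentation import SegmentationConfig, segment_matrix
from .simulate import (GenomeLayout, NoiseModel, PhenotypeModel, TruthSet,
                       effect_for_variance_explained, plant_cohort_cnvs,
                       simulate_phenotypes, simulate_probes, simulate_signal)
from .traits import ALL_TRAITS, block_of

__all__ = [
    "PipelineConfig",
    "demo_config",
    "run_simulate",
    "run_segment",
    "run_call",
    "run_associate",
    "run_annotate",
    "run_all",
]


@dataclass
class PipelineConfig:
    """Everything one run needs; YAML round-trippable via to/from_yaml."""

    outdir: str
    seed: int
    simulate: dict = field(default_factory=dict)  # empty -> ingest existing files
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)
    calling: CallingConfig = field(default_factory=CallingConfig)
    association: dict = field(default_factory=lambda: {
        "family": "per_trait", "use_expected_dosage": True, "alpha": 0.05,
    })
    annotation: AnnotationConfig = field(default_factory=AnnotationConfig)
    genes_path: str | None = None
    genes_dialect: str = "gff3"
    qtls_path: str | None = None
    qtls_dialect: str = "tsv1"
    external_cnvrs_path: str | None = None

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("segmentation"), dict):
            seg = dict(d["segmentation"])
            if isinstance(seg.get("penalty_grid"), list):
                seg["penalty_grid"] = tuple(seg["penalty_grid"])
            d["segmentation"] = SegmentationConfig(**seg)
        if isinstance(d.get("calling"), dict):
            d["calling"] = CallingConfig(**d["calling"])
        if isinstance(d.get("annotation"), dict):
            d["annotation"] = AnnotationConfig(**d["annotation"])
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    # -- provenance ---------------------------------------------------------
    def config_hash(self) -> str:
        """Hash of the scientific parameters only (the run directory is a
        location, not a parameter, and must not change provenance)."""
        d = self.to_dict()
        d.pop("outdir", None)
        blob = yaml.safe_dump(d, sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]

    def header_lines(self) -> list[str]:
        return [f"arraycnv {__version__} seed={self.seed} "
                f"config={self.config_hash()}"]

    # -- paths --------------------------------------------------------------
    def path(self, name: str) -> Path:
        return Path(self.outdir) / name


def demo_config(outdir: str | Path, seed: int = 1) -> PipelineConfig:
    """The packaged demo cohort: 4 chromosomes × ~5,000 probes (1.2 kb
    spacing), 47 male samples against a female reference, 30 planted CNVR
    loci on the autosomes, 8 traits with two planted dosage effects."""
    return PipelineConfig(
        outdir=str(outdir),
        seed=int(seed),
        simulate={
            "chromosomes": [["chr1", 6_000_000], ["chr2", 6_000_000],
                            ["chr3", 6_000_000], ["chrX", 6_000_000]],
            "probe_spacing_bp": 1200.0,
            "sex_chromosome": "chrX",
            "n_samples": 47,
            "sample_sex": "male",
            "n_cnv_loci": 30,
            "probes_per_locus": [5, 40],
            "carrier_freq": [0.1, 0.5],
            "copy_states": [1, 3],
            "cnv_chromosomes": ["chr1", "chr2", "chr3"],
            "probe_sd": 0.15,
            "sample_shift_sd": 0.05,
            "traits": ["Milk", "Protein", "Net_Merit", "Dtr_Preg_Rate",
                       "Heifer_Conc_Rate", "SCS", "livability", "rump_width"],
            "trait_rho": 0.6,
            "residual_sd": 1.0,
            "effects": [
                {"locus_rank": 0, "trait": "Dtr_Preg_Rate",
                 "variance_explained": 0.30},
                {"locus_rank": 1, "trait": "Milk",
                 "variance_explained": 0.15},
            ],
        },
        segmentation=SegmentationConfig(penalty=0.26),
    )


# ---------------------------------------------------------------------------
# stage helpers
# ---------------------------------------------------------------------------

def _require(cfg: PipelineConfig, name: str, stage: str) -> Path:
    p = cfg.path(name)
    if not p.exists():
        raise FileNotFoundError(
            f"missing {p}; run the '{stage}' stage first"
        )
    return p


def _trait_correlation(trait_names: list[str], rho: float) -> np.ndarray:
    n = len(trait_names)
    R = np.eye(n)
    for i in range(n):
        for j in range(n):
            if i != j and block_of(trait_names[i]) == block_of(trait_names[j]):
                R[i, j] = rho
    return R


def _layout_from_cfg(sim: dict) -> GenomeLayout:
    return GenomeLayout(
        chromosomes=tuple((str(c), int(L)) for c, L in sim["chromosomes"]),
        probe_spacing_bp=float(sim.get("probe_spacing_bp", 1200.0)),
        sex_chromosome=sim.get("sex_chromosome"),
    )


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def run_simulate(cfg: PipelineConfig) -> dict:
    """Generate the cohort: signal matrix, truth BED, effects table, traits."""
    sim = cfg.simulate
    if not sim:
        raise ValueError("config has no 'simulate' section; supply input files")
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    t0 = time.perf_counter()
    layout = _layout_from_cfg(sim)
    samples = [f"S{i + 1:02d}" for i in range(int(sim["n_samples"]))]
    sexes = {s: sim.get("sample_sex", "male") for s in samples}

    probes = simulate_probes(layout, cfg.seed)
    cnvs = plant_cohort_cnvs(
        probes, samples, cfg.seed,
        n_loci=int(sim.get("n_cnv_loci", 30)),
        probes_per_locus=tuple(sim.get("probes_per_locus", (5, 40))),
        carrier_freq=tuple(sim.get("carrier_freq", (0.1, 0.5))),
        copy_states=tuple(sim.get("copy_states", (1, 3))),
        chromosomes=sim.get("cnv_chromosomes"),
    )
    noise = NoiseModel(probe_sd=float(sim.get("probe_sd", 0.15)),
                       sample_shift_sd=float(sim.get("sample_shift_sd", 0.05)))
    sm = simulate_signal(probes, cnvs, noise, cfg.seed, samples=samples,
                         sex_chromosome=layout.sex_chromosome,
                         sample_sex=sexes)

    # default phenotype set: the full 41-trait PTA catalogue
    trait_names = list(sim.get("traits", ALL_TRAITS))
    loci: list[tuple[str, int, int]] = []
    for cnv in cnvs:
        if cnv.locus not in loci:
            loci.append(cnv.locus)
    effects: dict[tuple[tuple[str, int, int], str], float] = {}
    residual_sd = float(sim.get("residual_sd", 1.0))
    truth = TruthSet(tuple(cnvs), effects, cfg.seed)
    # effects are planted on loci ranked by descending carrier count, so
    # rank 0 is the most polymorphic (and hence genotypable) locus
    n_carriers = {loc: 0 for loc in loci}
    for cnv in cnvs:
        n_carriers[cnv.locus] += 1
    ranked = sorted(loci, key=lambda L: (-n_carriers[L], L))
    for eff in sim.get("effects", []):
        locus = ranked[int(eff["locus_rank"])]
        dosages = [truth.copy_number(s, locus) for s in samples]
        if "beta" in eff:
            beta = float(eff["beta"])
        else:
            beta = effect_for_variance_explained(
                float(eff["variance_explained"]), dosages, residual_sd
            )
        effects[(locus, str(eff["trait"]))] = beta
    model = PhenotypeModel(
        trait_names=tuple(trait_names),
        dosage_effects=effects,
        residual_sd=residual_sd,
        trait_correlation=_trait_correlation(trait_names,
                                             float(sim.get("trait_rho", 0.6)))
        if trait_names else None,
    )
    traits_wide = simulate_phenotypes(samples, truth, model, cfg.seed)

    hdr = cfg.header_lines()
    sm.write(cfg.path("signal.tsv"), hdr)
    write_bed(sorted(cnvs, key=lambda c: (c.chrom, c.start_bp, c.sample_id)),
              cfg.path("truth.bed"), hdr)
    eff_rows = [{"chrom": loc[0], "start_bp": loc[1], "end_bp": loc[2],
                 "trait": tr, "beta": b} for (loc, tr), b in effects.items()]
    write_results_tsv(pd.DataFrame(eff_rows, columns=["chrom", "start_bp",
                                                      "end_bp", "trait", "beta"]),
                      cfg.path("truth_effects.tsv"), hdr)
    write_results_tsv(traits_to_long(traits_wide), cfg.path("traits.tsv"), hdr)
    sexes_df = pd.DataFrame({"sample_id": samples,
                             "sex": [sexes[s] for s in samples]})
    write_results_tsv(sexes_df, cfg.path("samples.tsv"), hdr)

    return {
        "stage": "simulate",
        "n_probes": int(len(probes)),
        "n_samples": len(samples),
        "n_true_cnvs": len(cnvs),
        "n_true_loci": len(loci),
        "n_traits": len(trait_names),
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }


def run_segment(cfg: PipelineConfig) -> dict:
    t0 = time.perf_counter()
    _require(cfg, "signal.tsv", "simulate")
    sm = read_signal_matrix(cfg.path("signal.tsv"))
    sex_chrom = cfg.simulate.get("sex_chromosome") if cfg.simulate else None
    sample_sex = None
    if cfg.path("samples.tsv").exists():
        sdf = pd.read_csv(cfg.path("samples.tsv"), sep="\t", comment="#")
        sample_sex = dict(zip(sdf["sample_id"].astype(str), sdf["sex"]))
    segs = segment_matrix(sm, cfg.segmentation, sex_chromosome=sex_chrom,
                          sample_sex=sample_sex)
    write_results_tsv(segs, cfg.path("segments.tsv"), cfg.header_lines())
    return {
        "stage": "segment",
        "n_segments": int(len(segs)),
        "penalty": cfg.segmentation.penalty,
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }


def run_call(cfg: PipelineConfig) -> dict:
    t0 = time.perf_counter()
    _require(cfg, "segments.tsv", "segment")
    segs = pd.read_csv(cfg.path("segments.tsv"), sep="\t", comment="#")
    raw_calls = call_cnvs_from_table(segs, cfg.calling)
    calls = filter_cnvs(raw_calls, cfg.calling)
    cnvrs = merge_to_cnvrs(calls)
    chrom_lengths = None
    if cfg.simulate:
        chrom_lengths = {str(c): int(L) for c, L in cfg.simulate["chromosomes"]}
    summary = summarize_cnvs(calls, cnvrs, chrom_lengths)

    hdr = cfg.header_lines()
    write_results_tsv(calls_to_frame(calls), cfg.path("calls.tsv"), hdr)
    write_bed(calls, cfg.path("calls.bed"), hdr)
    write_results_tsv(cnvrs_to_frame(cnvrs), cfg.path("cnvrs.tsv"), hdr)
    write_bed(cnvrs, cfg.path("cnvrs.bed"), hdr)
    return {
        "stage": "call",
        "n_raw_calls": len(raw_calls),
        "n_calls": len(calls),
        "n_cnvrs": len(cnvrs),
        "cnvr_state_counts": summary["cnvr_state_counts"],
        "total_cnvr_bp": summary["total_cnvr_bp"],
        "genome_cnvr_fraction": summary["genome_cnvr_fraction"],
        "mean_events_per_sample": summary["mean_events_per_sample"],
        "thresholds": asdict(cfg.calling),
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }


def _read_cnvrs(cfg: PipelineConfig) -> list[CnvRegion]:
    df = pd.read_csv(cfg.path("cnvrs.tsv"), sep="\t", comment="#",
                     dtype={"chrom": str})
    calls_df = pd.read_csv(cfg.path("calls.tsv"), sep="\t", comment="#",
                           dtype={"chrom": str})
    regions = []
    for r in df.itertuples():
        members = calls_df[
            (calls_df["chrom"] == r.chrom)
            & (calls_df["start_bp"] >= r.start_bp)
            & (calls_df["end_bp"] <= r.end_bp)
        ]
        member_calls = tuple(
            CnvCall(str(m.sample), m.chrom, int(m.start_bp), int(m.end_bp),
                    m.state, float(m.mean_log2), int(m.n_probes))
            for m in members.itertuples()
        )
        regions.append(CnvRegion(str(r.cnvr_id), str(r.chrom),
                                 int(r.start_bp), int(r.end_bp), str(r.state),
                                 member_calls))
    return regions


def run_associate(cfg: PipelineConfig) -> dict:
    t0 = time.perf_counter()
    _require(cfg, "signal.tsv", "simulate")
    _require(cfg, "cnvrs.tsv", "call")
    _require(cfg, "traits.tsv", "simulate")
    sm = read_signal_matrix(cfg.path("signal.tsv"))
    cnvrs = _read_cnvrs(cfg)
    traits_wide = traits_to_wide(read_trait_table(cfg.path("traits.tsv")))
    table, info = run_association(
        sm, cnvrs, traits_wide, cfg.seed,
        use_expected_dosage=bool(cfg.association.get("use_expected_dosage", True)),
        family=str(cfg.association.get("family", "per_trait")),
        alpha=float(cfg.association.get("alpha", 0.05)),
    )
    write_results_tsv(table, cfg.path("association.tsv"), cfg.header_lines())
    n_sig = int(table["significant"].fillna(False).sum()) if len(table) else 0
    sig_cnvrs = sorted(table.loc[table["significant"].fillna(False),
                                 "cnvr_id"].unique()) if len(table) else []
    return {
        "stage": "associate",
        "n_cnvrs_tested": info["n_cnvrs_tested"],
        "n_converged": info["n_converged"],
        "bonferroni_family_size": info["bonferroni_family_size"],
        "n_significant_pairs": n_sig,
        "significant_cnvrs": list(map(str, sig_cnvrs)),
        "wall_time_s": round(time.perf_counter() - t0, 3),
    }


def run_annotate(cfg: PipelineConfig) -> dict:
    t0 = time.perf_counter()
    _require(cfg, "cnvrs.tsv", "call")
    cnvrs = _read_cnvrs(cfg)
    hdr = cfg.header_lines()
    out: dict = {"stage": "annotate", "n_cnvrs": len(cnvrs)}
    if cfg.genes_path:
        genes = read_genes(cfg.genes_path, cfg.genes_dialect)
        recs = overlap_genes(cnvrs, genes, cfg.annotation.gene_flank_bp)
        df = pd.DataFrame([vars(r) for r in recs])
        write_results_tsv(df, cfg.path("gene_overlaps.tsv"), hdr)
        out["n_gene_overlap_records"] = len(recs)
    if cfg.qtls_path:
        qtls = read_qtls(cfg.qtls_path, cfg.qtls_dialect)
        recs = overlap_qtls(cnvrs, qtls, cfg.annotation)
        df = pd.DataFrame([vars(r) for r in recs])
        write_results_tsv(df, cfg.path("qtl_overlaps.tsv"), hdr)
        out["n_qtl_overlap_records"] = len(recs)
    if cfg.external_cnvrs_path:
        from .io import read_intervals
        ext = read_intervals(cfg.external_cnvrs_path, "bed")
        table, summary = compare_cnvr_sets(
            cnvrs, ext, cfg.annotation.set_compare_min_fraction
        )
        write_results_tsv(table, cfg.path("set_comparison.tsv"), hdr)
        out["set_comparison"] = summary
    out["wall_time_s"] = round(time.perf_counter() - t0, 3)
    return out


def run_all(cfg: PipelineConfig) -> dict:
    """Execute every stage in order and write report.json.

    The report's arithmetic identities (state counts summing to the CNVR
    total) are checked on every run.
    """
    Path(cfg.outdir).mkdir(parents=True, exist_ok=True)
    report: dict = {
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": cfg.config_hash(),
        "stages": [],
    }
    stages = [run_simulate, run_segment, run_call, run_associate]
    if cfg.genes_path or cfg.qtls_path or cfg.external_cnvrs_path:
        stages.append(run_annotate)
    for stage in stages:
        frag = stage(cfg)
        report["stages"].append(frag)
        if frag["stage"] == "call":
            counts = frag["cnvr_state_counts"]
            if sum(counts.values()) != frag["n_cnvrs"]:
                raise AssertionError("CNVR state counts do not sum to total")
    with open(cfg.path("report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
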