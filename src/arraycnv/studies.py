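"""Seeded simulation studies of the pipeline's operating characteristics.

These drive the package end to end on small synthetic cohorts and measure
what a methods evaluation would measure: planted-CNV recall, self-to-self
false-positive counts, mixture-genotyping accuracy, association type-I
error and slope recovery, variance-explained calibration, and end-to-end
detection power at the study's cohort size (47 samples).  Problem sizes are
desk-scale by design (hundreds to a few thousand probes per profile); the
quantities they estimate are rates and biases, not genome-scale counts.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .association import CnvrSignal, associate, genotype_cnvr, run_association
from .calling import CallingConfig, call_cnvs, filter_cnvs, merge_to_cnvrs
from .segmentation import SegmentationConfig, segment_profile
from .simulate import (GenomeLayout, NoiseModel, PhenotypeModel, TrueCnv,
                       TruthSet, effect_for_variance_explained,
                       simulate_phenotypes, simulate_probes,
                       simulate_self_self, simulate_signal)

__all__ = [
    "mixture_recovery",
    "association_type1_error",
    "slope_recovery",
    "ve_design_estimate",
    "endtoend_power",
    "self_self_false_positives",
]

_DOSAGE_PROBS = (0.3, 0.4, 0.3)  # P(copy number 1 / 2 / 3) at a polymorphic locus


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(int(seed))
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in ss.spawn(n)]


# ---------------------------------------------------------------------------
# mixture genotyping
# ---------------------------------------------------------------------------

def mixture_recovery(n_replicates: int = 50, seed: int = 0, n: int = 150,
                     means=(-1.0, 0.0, 0.585), sd: float = 0.05
                     ) -> np.ndarray:
    """Fraction of samples assigned their generating class, per replicate.

    Three equal clusters at the canonical loss/neutral/gain score levels.
    """
    accs = []
    for rep_seed in _child_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        per = n // len(means)
        truth = np.repeat(np.arange(1, len(means) + 1), per)
        x = np.concatenate([
            rng.normal(m, sd, per) for m in means
        ])
        sig = CnvrSignal("sim", pd.Series(x, index=[f"S{i}" for i in range(len(x))]))
        fit, assigns = genotype_cnvr(sig, rep_seed)
        got = np.array([a.genotype_class for a in assigns])
        accs.append(float(np.mean(got == truth)))
    return np.asarray(accs)


# ---------------------------------------------------------------------------
# association calibration
# ---------------------------------------------------------------------------

def _draw_dosage(rng: np.random.Generator, n: int) -> np.ndarray:
    return rng.choice([1.0, 2.0, 3.0], size=n, p=_DOSAGE_PROBS)


def association_type1_error(n_replicates: int = 1000, seed: int = 0,
                            n: int = 47) -> np.ndarray:
    """Null p-values: trait independent of dosage, one test per replicate."""
    pvals = []
    for rep_seed in _child_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        d = pd.Series(_draw_dosage(rng, n),
                      index=[f"S{i}" for i in range(n)], name="null")
        y = pd.Series(rng.normal(size=n), index=d.index)
        pvals.append(associate(d, y, "null").p_value)
    return np.asarray(pvals)


def slope_recovery(n_replicates: int = 200, seed: int = 0, n: int = 500,
                   beta: float = 1.0, residual_sd: float = 1.0) -> np.ndarray:
    """Estimated regression slopes for a planted dosage effect."""
    betas = []
    for rep_seed in _child_seeds(seed, n_replicates):
        rng = np.random.default_rng(rep_seed)
        d = _draw_dosage(rng, n)
        y = beta * (d - 2.0) + rng.normal(0.0, residual_sd, n)
        idx = [f"S{i}" for i in range(n)]
        res = associate(pd.Series(d, index=idx, name="locus"),
                        pd.Series(y, index=idx), "trait")
        betas.append(res.beta)
    return np.asarray(betas)


def ve_design_estimate(target_ve: float = 0.143, n: int = 500,
                       seed: int = 0) -> float:
    """Realized squared dosage–trait correlation for a locus designed (via
    the closed-form variance partition) to explain ``target_ve``."""
    rng = np.random.default_rng(int(seed))
    d = _draw_dosage(rng, n)
    beta = effect_for_variance_explained(target_ve, d, 1.0)
    y = beta * (d - 2.0) + rng.normal(0.0, 1.0, n)
    r = np.corrcoef(d, y)[0, 1]
    return float(r ** 2)


# ---------------------------------------------------------------------------
# end-to-end power at the study's cohort size
# ---------------------------------------------------------------------------

def _power_replicate(rep_seed: int, n_samples: int, target_ve: float,
                     probe_sd: float, penalty: float) -> bool:
    """One full signal → segmentation → calling → association replicate.

    One chromosome of 300 probes carries a single 20-probe CNVR whose
    dosage explains ``target_ve`` of one trait's variance.  Returns True
    when that CNVR reaches Bonferroni-corrected significance for that
    trait.
    """
    rng = np.random.default_rng(rep_seed)
    layout = GenomeLayout((("chr1", 360_000),), probe_spacing_bp=1200.0)
    probes = simulate_probes(layout, rep_seed, jitter_frac=0.0)
    pos = probes["pos"].to_numpy()
    first, last = 100, 119  # 20-probe locus
    locus = ("chr1", int(pos[first]), int(pos[last]))

    samples = [f"S{i + 1:02d}" for i in range(n_samples)]
    cn = _draw_dosage(rng, n_samples).astype(int)
    cnvs = [
        TrueCnv(s, locus[0], locus[1], locus[2], int(c))
        for s, c in zip(samples, cn) if c != 2
    ]
    beta = effect_for_variance_explained(target_ve, cn, 1.0)
    truth = TruthSet(tuple(cnvs), {(locus, "Dtr_Preg_Rate"): beta}, rep_seed)
    model = PhenotypeModel(trait_names=("Dtr_Preg_Rate",),
                           dosage_effects=truth.true_effects, residual_sd=1.0)
    traits = simulate_phenotypes(samples, truth, model, rep_seed)

    sm = simulate_signal(probes, cnvs, NoiseModel(probe_sd, 0.05), rep_seed,
                         samples=samples)
    seg_cfg = SegmentationConfig(penalty=penalty)
    call_cfg = CallingConfig()
    calls = []
    for j, s in enumerate(samples):
        col = sm.values[:, j] - np.median(sm.values[:, j])
        segs = segment_profile(col, pos, seg_cfg, chrom="chr1")
        calls.extend(filter_cnvs(call_cnvs(segs, call_cfg, s), call_cfg))
    cnvrs = merge_to_cnvrs(calls)
    hit = [r for r in cnvrs
           if r.chrom == locus[0] and r.start_bp <= locus[2]
           and r.end_bp >= locus[1]]
    if not hit:
        return False
    table, info = run_association(sm, cnvrs, traits, rep_seed)
    if table.empty:
        return False
    sig = table[(table["trait"] == "Dtr_Preg_Rate")
                & table["significant"].fillna(False)]
    hit_ids = {r.cnvr_id for r in hit}
    return bool(sig["cnvr_id"].isin(hit_ids).any())


def endtoend_power(n_replicates: int = 200, seed: int = 0,
                   n_samples: int = 47, target_ve: float = 0.20,
                   probe_sd: float = 0.15, penalty: float = 0.26) -> float:
    """Detection power for a planted CNVR–trait effect at cohort size 47."""
    hits = [
        _power_replicate(s, n_samples, target_ve, probe_sd, penalty)
        for s in _child_seeds(seed, n_replicates)
    ]
    return float(np.mean(hits))


# ---------------------------------------------------------------------------
# self-to-self false positives
# ---------------------------------------------------------------------------

def self_self_false_positives(seed: int = 0, n_probes: int = 2000,
                              n_samples: int = 3, probe_sd: float = 0.15,
                              penalty: float = 0.26) -> int:
    """CNV calls on noise-only hybridizations (expected: 0 at default noise).

    With the 0.5_5 rule, five neighbouring probes must each sit ~3.3 SDs
    from baseline, so the per-window false-call probability is vanishing.
    """
    layout = GenomeLayout((("chr1", int(n_probes * 1200)),),
                          probe_spacing_bp=1200.0)
    probes = simulate_probes(layout, seed, jitter_frac=0.0)
    sm = simulate_self_self(probes, NoiseModel(probe_sd, 0.05), seed,
                            n_samples=n_samples)
    pos = probes["pos"].to_numpy()
    cfg = SegmentationConfig(penalty=penalty)
    call_cfg = CallingConfig()
    total = 0
    for j, s in enumerate(sm.samples):
        col = sm.values[:, j] - np.median(sm.values[:, j])
        segs = segment_profile(col, pos, cfg, chrom="chr1")
        total += len(filter_cnvs(call_cnvs(segs, call_cfg, s), call_cfg))
    return total
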