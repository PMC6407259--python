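"""CNVR–trait association: PCA signal reduction, mixture genotyping,
regression testing, Bonferroni correction, variance explained, trait
clustering.

For each CNVR the member probes' log2 ratios are collapsed to a
one-dimensional per-sample score (first principal component, oriented to
correlate positively with the mean probe signal).  A univariate Gaussian
mixture with 1–3 components is fitted to the scores by EM (deterministic
quantile initialization plus seeded random restarts, component count by
BIC); samples get an ordered copy-number genotype class in {1, 2, 3} and a
posterior-expected dosage.  CNVRs whose mixture does not converge to at
least two well-separated, adequately weighted components are excluded from
testing — mirroring how association studies drop loci whose genotyping
fails to converge.  Converged CNVRs are tested trait-by-trait with ordinary
least squares of PTA on dosage; p-values are Bonferroni-corrected within a
configurable family (default: per trait, across converged CNVRs), and
variance explained is reported as the squared Pearson correlation between
the one-dimensional signal and the trait.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.special import logsumexp

from .calling import CnvRegion, is_placed_chromosome
from .io import SignalMatrix

__all__ = [
    "CnvrSignal",
    "MixtureFit",
    "GenotypeAssignment",
    "AssociationResult",
    "EmConfig",
    "extract_cnvr_signal",
    "genotype_cnvr",
    "associate",
    "bonferroni_correct",
    "variance_explained",
    "cluster_traits",
    "run_association",
    "plot_manhattan",
]

_LOG_2PI = float(np.log(2.0 * np.pi))


# ---------------------------------------------------------------------------
# types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CnvrSignal:
    """One-dimensional per-sample score for a CNVR.

    ``orientation`` is +1 when the raw first PC already correlated
    positively with the mean member-probe log2 ratio, −1 if it was flipped.
    """

    cnvr_id: str
    scores: pd.Series  # indexed by sample_id
    orientation: int = 1


@dataclass(frozen=True)
class EmConfig:
    max_components: int = 3
    max_iter: int = 500
    tol: float = 1e-8
    sd_floor: float = 1e-3
    mean_sep_floor: float = 0.5   # in units of pooled sd
    n_restarts: int = 5


@dataclass(frozen=True)
class MixtureFit:
    """A fitted 1-D Gaussian mixture, components sorted by mean."""

    n_components: int
    means: tuple[float, ...]
    sds: tuple[float, ...]
    weights: tuple[float, ...]
    log_likelihood: float
    bic: float
    converged: bool
    seed: int


@dataclass(frozen=True)
class GenotypeAssignment:
    """Per-sample copy-number genotype for one CNVR.

    ``genotype_class`` ∈ {1, 2, 3}, ordered by component mean (1 = lowest
    signal; 2 is the modal/baseline class); ``expected_dosage`` is the
    posterior-weighted class value.
    """

    cnvr_id: str
    sample_id: str
    genotype_class: int
    posteriors: tuple[float, ...]
    expected_dosage: float


@dataclass(frozen=True)
class AssociationResult:
    cnvr_id: str
    trait: str
    n: int
    beta: float
    se: float
    p_value: float
    converged: bool
    testable: bool = True
    p_bonferroni: float | None = None
    significant: bool | None = None
    variance_explained: float | None = None


# ---------------------------------------------------------------------------
# signal extraction
# ---------------------------------------------------------------------------

def extract_cnvr_signal(sm: SignalMatrix, cnvr: CnvRegion) -> CnvrSignal:
    """First-PC score per sample over the CNVR's member probes.

    With a single probe the score is that probe's row.  The sign is fixed
    so the score correlates positively with each sample's mean member-probe
    log2 ratio, making downstream genotype classes comparable across CNVRs.
    """
    chrom = sm.probes["chrom"].to_numpy(dtype=object)
    pos = sm.probes["pos"].to_numpy()
    mask = (chrom == cnvr.chrom) & (pos >= cnvr.start_bp) & (pos <= cnvr.end_bp)
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        raise ValueError(f"no probes inside {cnvr.cnvr_id} "
                         f"({cnvr.chrom}:{cnvr.start_bp}-{cnvr.end_bp})")
    X = sm.values[idx, :].T  # samples x probes
    # probe-wise complete: drop probes with any missing sample
    complete = ~np.isnan(X).any(axis=0)
    if not complete.any():
        raise ValueError(f"all member probes of {cnvr.cnvr_id} have missing values")
    X = X[:, complete]
    mean_signal = X.mean(axis=1)
    if X.shape[1] == 1:
        return CnvrSignal(cnvr.cnvr_id,
                          pd.Series(X[:, 0], index=sm.samples), 1)
    Xc = X - X.mean(axis=0, keepdims=True)
    # first right-singular direction of the sample x probe matrix
    u, s, vt = np.linalg.svd(Xc, full_matrices=False)
    scores = Xc @ vt[0]
    orientation = 1
    if np.std(scores) > 0 and np.std(mean_signal) > 0:
        r = np.corrcoef(scores, mean_signal)[0, 1]
        if r < 0:
            scores, orientation = -scores, -1
    return CnvrSignal(cnvr.cnvr_id, pd.Series(scores, index=sm.samples),
                      orientation)


# ---------------------------------------------------------------------------
# EM mixture genotyping
# ---------------------------------------------------------------------------

def _em_once(x, means, sds, weights, cfg: EmConfig):
    n, k = len(x), len(means)
    means = np.array(means, float)
    sds = np.maximum(np.array(sds, float), cfg.sd_floor)
    weights = np.array(weights, float)
    weights /= weights.sum()
    ll_old = -np.inf
    converged = False
    for _ in range(cfg.max_iter):
        log_comp = (
            np.log(weights)[None, :]
            - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
            - np.log(sds)[None, :] - 0.5 * _LOG_2PI
        )
        log_norm = logsumexp(log_comp, axis=1)
        ll = float(log_norm.sum())
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.maximum(np.sqrt(var), cfg.sd_floor)
        weights = nk / n
        if abs(ll - ll_old) < cfg.tol:
            converged = True
            break
        ll_old = ll
    order = np.argsort(means)
    return means[order], sds[order], weights[order], ll, converged


def _fit_k(x, k, cfg: EmConfig, rng: np.random.Generator):
    """Best-of-restarts EM fit with k components."""
    n = len(x)
    overall_sd = max(float(np.std(x)), cfg.sd_floor)
    q = np.quantile(x, (np.arange(k) + 0.5) / k)
    inits = [q]
    for _ in range(cfg.n_restarts):
        inits.append(q + rng.normal(0.0, overall_sd / 2.0, size=k))
    best = None
    for m0 in inits:
        fit = _em_once(x, np.sort(m0), [overall_sd / k] * k, [1.0 / k] * k, cfg)
        if best is None or fit[3] > best[3]:
            best = fit
    return best


def genotype_cnvr(signal: CnvrSignal, seed: int,
                  cfg: EmConfig | None = None
                  ) -> tuple[MixtureFit, list[GenotypeAssignment]]:
    """Fit 1–3 component Gaussian mixtures to the scores and assign
    genotypes.

    Component count is chosen by BIC.  The fit is flagged converged only
    when EM converged, every component weight is ≥ 2/n, adjacent means are
    ≥ ``mean_sep_floor`` pooled SDs apart, and at least two components were
    resolved — a 1-component pick on non-degenerate scores means the CNVR's
    copy classes could not be separated and is excluded from testing.
    Degenerate (zero-variance) scores yield a trivially converged
    1-component fit with everyone in the baseline class 2.
    """
    cfg = cfg or EmConfig()
    x = signal.scores.to_numpy(dtype=float)
    keep = np.isfinite(x)
    x = x[keep]
    sample_ids = list(signal.scores.index[keep])
    n = len(x)
    if n < 10:
        raise ValueError("need at least 10 samples with scores to genotype")
    rng = np.random.default_rng(int(seed))

    if float(np.std(x)) < cfg.sd_floor:
        fit = MixtureFit(1, (float(np.mean(x)),), (cfg.sd_floor,), (1.0,),
                         0.0, 0.0, True, int(seed))
        assigns = [GenotypeAssignment(signal.cnvr_id, s, 2, (1.0,), 2.0)
                   for s in sample_ids]
        return fit, assigns

    fits = {}
    for k in range(1, cfg.max_components + 1):
        means, sds, weights, ll, em_ok = _fit_k(x, k, cfg, rng)
        bic = -2.0 * ll + (3 * k - 1) * np.log(n)
        fits[k] = (means, sds, weights, ll, em_ok, bic)

    # model selection ignores degenerate fits (an SD clamped at the floor or
    # a component holding fewer than ~2 samples is a likelihood spike, not a
    # copy-number class); if nothing is admissible, fall back to raw BIC
    def admissible(k):
        means, sds, weights, *_ = fits[k]
        return all(w >= 2.0 / n for w in weights) and all(s > cfg.sd_floor
                                                          for s in sds)

    candidates = [k for k in fits if admissible(k)] or list(fits)
    k_best = min(candidates, key=lambda k: (fits[k][5], k))
    means, sds, weights, ll, em_ok, bic = fits[k_best]

    pooled_sd = float(np.sqrt(np.sum(weights * sds ** 2)))
    min_weight = 2.0 / n
    sep_ok = all(
        (means[i + 1] - means[i]) >= cfg.mean_sep_floor * pooled_sd
        for i in range(k_best - 1)
    )
    weight_ok = all(w >= min_weight for w in weights)
    converged = bool(em_ok and sep_ok and weight_ok and k_best >= 2)

    fit = MixtureFit(k_best, tuple(map(float, means)), tuple(map(float, sds)),
                     tuple(map(float, weights)), float(ll), float(bic),
                     converged, int(seed))

    class_values = _class_values(means, weights, x)
    log_comp = (
        np.log(np.maximum(weights, 1e-300))[None, :]
        - 0.5 * ((x[:, None] - means[None, :]) / sds[None, :]) ** 2
        - np.log(sds)[None, :] - 0.5 * _LOG_2PI
    )
    resp = np.exp(log_comp - logsumexp(log_comp, axis=1)[:, None])
    hard = np.argmax(resp, axis=1)
    dosage = resp @ np.asarray(class_values, dtype=float)
    assigns = [
        GenotypeAssignment(signal.cnvr_id, s, int(class_values[hard[i]]),
                           tuple(map(float, resp[i])), float(dosage[i]))
        for i, s in enumerate(sample_ids)
    ]
    return fit, assigns


def _class_values(means, weights, x) -> list[int]:
    """Map mean-sorted components to genotype classes in {1, 2, 3}.

    k=1 → [2]; k=3 → [1, 2, 3].  For k=2 the larger-weight component is the
    modal baseline (class 2) and the other is 1 (lower mean) or 3 (higher);
    a weight tie goes to the component whose mean is nearer the score
    median.
    """
    k = len(means)
    if k == 1:
        return [2]
    if k == 3:
        return [1, 2, 3]
    med = float(np.median(x))
    if weights[0] > weights[1]:
        base = 0
    elif weights[1] > weights[0]:
        base = 1
    else:
        base = int(np.argmin(np.abs(np.asarray(means) - med)))
    return [2, 3] if base == 0 else [1, 2]


# ---------------------------------------------------------------------------
# regression testing
# ---------------------------------------------------------------------------

def associate(assignments: Sequence[GenotypeAssignment] | pd.Series,
              trait_values: pd.Series, trait: str = "",
              *, use_expected_dosage: bool = True,
              weights: pd.Series | None = None,
              converged: bool = True) -> AssociationResult:
    """OLS of PTA on copy-number dosage for one (CNVR, trait) pair.

    ``assignments`` may be a list of :class:`GenotypeAssignment` or a
    pre-built dosage Series indexed by sample.  ``weights`` (e.g. PTA
    reliabilities) switch the fit to weighted least squares; with equal
    weights the result equals the OLS fit.  Constant dosage yields an
    untestable result (beta=0, p=1).
    """
    if isinstance(assignments, pd.Series):
        dosage = assignments
        cnvr_id = str(dosage.name) if dosage.name else ""
    else:
        cnvr_id = assignments[0].cnvr_id if assignments else ""
        key = (lambda a: a.expected_dosage) if use_expected_dosage \
            else (lambda a: float(a.genotype_class))
        dosage = pd.Series({a.sample_id: key(a) for a in assignments})

    common = dosage.index.intersection(trait_values.index)
    d = dosage.loc[common].to_numpy(dtype=float)
    y = trait_values.loc[common].to_numpy(dtype=float)
    w = np.ones_like(d) if weights is None \
        else weights.reindex(common).to_numpy(dtype=float)
    ok = np.isfinite(d) & np.isfinite(y) & np.isfinite(w) & (w > 0)
    d, y, w = d[ok], y[ok], w[ok]
    n = len(d)
    if n < 10:
        raise ValueError(f"need >= 10 paired observations, got {n}")
    if np.std(d) == 0 or np.std(y) == 0:
        return AssociationResult(cnvr_id, trait, n, 0.0, np.nan, 1.0,
                                 converged, testable=False)
    if weights is None:
        res = stats.linregress(d, y)
        beta, se, p = float(res.slope), float(res.stderr), float(res.pvalue)
        r2 = float(res.rvalue ** 2)
    else:
        sw = w.sum()
        dm, ym = (w * d).sum() / sw, (w * y).sum() / sw
        sxx = (w * (d - dm) ** 2).sum()
        sxy = (w * (d - dm) * (y - ym)).sum()
        syy = (w * (y - ym) ** 2).sum()
        beta = float(sxy / sxx)
        resid = y - ym - beta * (d - dm)
        sigma2 = (w * resid ** 2).sum() / (n - 2)
        se = float(np.sqrt(sigma2 / sxx))
        t = beta / se
        p = float(2.0 * stats.t.sf(abs(t), n - 2))
        r2 = float(sxy ** 2 / (sxx * syy))
    return AssociationResult(
        cnvr_id, trait, n, beta, se, p, converged, testable=True,
        variance_explained=r2,
    )


def bonferroni_correct(results: Sequence[AssociationResult],
                       family_size: int,
                       alpha: float = 0.05) -> list[AssociationResult]:
    """p_bonferroni = min(1, m·p); significance flag at corrected alpha."""
    if family_size < 1:
        raise ValueError("family_size must be >= 1")
    out = []
    for r in results:
        p_adj = min(1.0, family_size * r.p_value)
        out.append(replace(r, p_bonferroni=p_adj,
                           significant=bool(r.testable and p_adj < alpha)))
    return out


def variance_explained(signal_scores: pd.Series,
                       trait_values: pd.Series) -> float:
    """Squared Pearson correlation between signal and trait (sign-invariant)."""
    common = signal_scores.index.intersection(trait_values.index)
    x = signal_scores.loc[common].to_numpy(dtype=float)
    y = trait_values.loc[common].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValueError("need >= 3 paired observations")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("constant input; variance explained set to 0",
                      stacklevel=2)
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r ** 2)


# ---------------------------------------------------------------------------
# trait clustering
# ---------------------------------------------------------------------------

def cluster_traits(p_matrix: pd.DataFrame
                   ) -> tuple[np.ndarray, list[str], list[str]]:
    """Hierarchical clustering of traits from a CNVR × trait p-value matrix.

    P-values are transformed to −log10 before computing pairwise Pearson
    correlations between trait columns; distance = 1 − r, average linkage.
    A constant column is placed at maximal distance (2.0) with a warning.
    Returns (linkage matrix, trait names, leaf-ordered trait names).
    """
    if p_matrix.shape[1] < 2 or p_matrix.shape[0] < 2:
        raise ValueError("need >= 2 traits and >= 2 CNVRs")
    X = -np.log10(np.clip(p_matrix.to_numpy(dtype=float), 1e-300, 1.0))
    traits = list(p_matrix.columns)
    t = len(traits)
    sd = X.std(axis=0)
    if (sd == 0).any():
        bad = [traits[i] for i in np.flatnonzero(sd == 0)]
        warnings.warn(f"constant p-value column(s) {bad}; placed at maximal "
                      f"distance", stacklevel=2)
    D = np.zeros((t, t))
    for i in range(t):
        for j in range(i + 1, t):
            if sd[i] == 0 or sd[j] == 0:
                d = 2.0
            else:
                d = 1.0 - float(np.corrcoef(X[:, i], X[:, j])[0, 1])
            D[i, j] = D[j, i] = max(d, 0.0)
    Z = linkage(squareform(D, checks=False), method="average")
    order = [traits[i] for i in leaves_list(Z)]
    return Z, traits, order


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

def run_association(
    sm: SignalMatrix,
    cnvrs: Sequence[CnvRegion],
    traits_wide: pd.DataFrame,
    seed: int,
    *,
    em_config: EmConfig | None = None,
    use_expected_dosage: bool = True,
    family: str = "per_trait",
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, dict]:
    """Genotype every placed-chromosome CNVR and test it against every trait.

    Returns (tidy result table, info dict with converged CNVR ids and the
    Bonferroni family size).  ``family``: 'per_trait' corrects across the
    converged CNVRs within each trait (m = #converged); 'global' uses
    m = #converged × #traits.
    """
    em_config = em_config or EmConfig()
    ss = np.random.SeedSequence(int(seed))
    cnvr_seeds = {r.cnvr_id: int(s.generate_state(1)[0] % (2 ** 31))
                  for r, s in zip(cnvrs, ss.spawn(max(len(cnvrs), 1)))}

    signals: dict[str, CnvrSignal] = {}
    genotypes: dict[str, list[GenotypeAssignment]] = {}
    fits: dict[str, MixtureFit] = {}
    converged_ids: list[str] = []
    for r in cnvrs:
        if not is_placed_chromosome(r.chrom):
            continue
        sig = extract_cnvr_signal(sm, r)
        fit, assigns = genotype_cnvr(sig, cnvr_seeds[r.cnvr_id], em_config)
        signals[r.cnvr_id], fits[r.cnvr_id] = sig, fit
        genotypes[r.cnvr_id] = assigns
        if fit.converged:
            converged_ids.append(r.cnvr_id)

    m = len(converged_ids)
    if family == "global":
        m = m * traits_wide.shape[1]
    results: list[AssociationResult] = []
    for cid in converged_ids:
        for trait in traits_wide.columns:
            res = associate(genotypes[cid], traits_wide[trait], str(trait),
                            use_expected_dosage=use_expected_dosage)
            ve = variance_explained(signals[cid].scores, traits_wide[trait]) \
                if res.testable else 0.0
            results.append(replace(res, variance_explained=ve))
    if m >= 1 and results:
        results = bonferroni_correct(results, m, alpha)

    coords = {r.cnvr_id: r for r in cnvrs}
    table = pd.DataFrame([
        {"cnvr_id": r.cnvr_id, "chrom": coords[r.cnvr_id].chrom,
         "start_bp": coords[r.cnvr_id].start_bp,
         "end_bp": coords[r.cnvr_id].end_bp, "trait": r.trait, "n": r.n,
         "beta": r.beta, "se": r.se, "p": r.p_value,
         "p_bonferroni": r.p_bonferroni, "significant": r.significant,
         "converged": r.converged, "testable": r.testable,
         "variance_explained": r.variance_explained}
        for r in results
    ], columns=["cnvr_id", "chrom", "start_bp", "end_bp", "trait", "n",
                "beta", "se", "p", "p_bonferroni", "significant",
                "converged", "testable", "variance_explained"])
    info = {
        "n_cnvrs_tested": len(signals),
        "n_converged": len(converged_ids),
        "converged_cnvrs": converged_ids,
        "bonferroni_family_size": m,
        "fits": fits,
    }
    return table, info


def plot_manhattan(results: pd.DataFrame, trait: str, path,
                   chromosome_lengths: dict[str, int] | None = None) -> None:
    """Manhattan-style plot of −log10 p against genomic coordinate for one
    trait."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    from .io import natural_chrom_key

    sub = results[results["trait"] == trait].copy()
    if sub.empty:
        raise ValueError(f"no results for trait {trait!r}")
    chroms = sorted(sub["chrom"].unique(), key=natural_chrom_key)
    if chromosome_lengths is None:
        chromosome_lengths = {
            c: int(sub.loc[sub["chrom"] == c, "end_bp"].max()) for c in chroms
        }
    offset, offsets = 0, {}
    for c in chroms:
        offsets[c] = offset
        offset += chromosome_lengths.get(c, 0)
    x = sub.apply(lambda r: offsets[r["chrom"]] + r["start_bp"], axis=1)
    y = -np.log10(np.clip(sub["p"].to_numpy(dtype=float), 1e-300, 1.0))
    fig, ax = plt.subplots(figsize=(9, 3))
    colors = [chroms.index(c) % 2 for c in sub["chrom"]]
    ax.scatter(x, y, c=colors, cmap="tab10", s=12)
    ax.set_xlabel("genomic coordinate")
    ax.set_ylabel(r"$-\log_{10} P$")
    ax.set_title(trait)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
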