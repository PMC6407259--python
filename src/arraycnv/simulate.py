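"""Synthetic aCGH cohorts with known CNV and phenotype structure.

The generator emulates the study design this package targets: a two-colour
CGH array with ~1.2 kb mean probe spacing, a cohort of 47 bulls hybridized
against a single female reference (so male chrX sits at a log2 ratio of −1),
gain/loss segments spanning a few kb to a couple of Mb, self-to-self
noise-only hybridizations, and 41 block-correlated PTA phenotypes carrying
CNV dosage effects.

Emission model: a probe inside a planted CNV of absolute copy number ``cn``
has expected log2 ratio ``log2(cn / 2)`` (the reference contributes 2
copies); copy number 0 is emitted at a documented floor of −4 to avoid
infinities.  Noise is i.i.d. Gaussian per probe plus a per-sample baseline
shift — the standard working assumption for normalized aCGH log ratios.

All randomness flows from one integer seed through a named
``numpy.random.SeedSequence`` splitting scheme, so every output is
byte-identical across runs with the same seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SignalMatrix
from .traits import ALL_TRAITS, TRAIT_BLOCKS

__all__ = [
    "GenomeLayout",
    "TrueCnv",
    "NoiseModel",
    "PhenotypeModel",
    "TruthSet",
    "CN0_FLOOR_LOG2",
    "simulate_probes",
    "simulate_signal",
    "simulate_self_self",
    "simulate_phenotypes",
    "plant_cohort_cnvs",
    "block_correlation",
    "expected_variance_explained",
    "effect_for_variance_explained",
    "expected_log2",
]

#: log2 ratio emitted for copy number 0 (a true −inf), kept finite.
CN0_FLOOR_LOG2 = -4.0


# ---------------------------------------------------------------------------
# configuration types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GenomeLayout:
    """Chromosome names/lengths and the target mean probe spacing."""

    chromosomes: tuple[tuple[str, int], ...]
    probe_spacing_bp: float = 1200.0
    sex_chromosome: str | None = None

    def __post_init__(self):
        names = [c for c, _ in self.chromosomes]
        if len(set(names)) != len(names):
            raise ValueError("chromosome names must be unique")
        if any(length <= 0 for _, length in self.chromosomes):
            raise ValueError("chromosome lengths must be positive")
        if self.probe_spacing_bp <= 0:
            raise ValueError("probe_spacing_bp must be positive")
        if self.sex_chromosome is not None and self.sex_chromosome not in names:
            raise ValueError(f"sex chromosome {self.sex_chromosome!r} not in layout")

    def length_of(self, chrom: str) -> int:
        for name, length in self.chromosomes:
            if name == chrom:
                return length
        raise KeyError(chrom)

    @property
    def autosomes(self) -> list[str]:
        return [c for c, _ in self.chromosomes if c != self.sex_chromosome]


@dataclass(frozen=True)
class TrueCnv:
    """A planted copy-number event in one sample (1-based inclusive bp).

    ``copy_number`` is the absolute copy count in the test sample; the
    diploid baseline is 2 on autosomes and 1 on the sex chromosome of male
    samples.
    """

    sample_id: str
    chrom: str
    start_bp: int
    end_bp: int
    copy_number: int

    def __post_init__(self):
        if self.start_bp > self.end_bp:
            raise ValueError("start_bp must be <= end_bp")
        if self.copy_number < 0:
            raise ValueError("copy_number must be non-negative")

    @property
    def locus(self) -> tuple[str, int, int]:
        return (self.chrom, self.start_bp, self.end_bp)

    @property
    def length_bp(self) -> int:
        return self.end_bp - self.start_bp + 1

    def bed_name(self) -> str:
        return f"{self.sample_id}:{self.copy_number}"


@dataclass(frozen=True)
class NoiseModel:
    probe_sd: float = 0.15
    sample_shift_sd: float = 0.05

    def __post_init__(self):
        if self.probe_sd < 0 or self.sample_shift_sd < 0:
            raise ValueError("noise SDs must be >= 0")


@dataclass(frozen=True)
class PhenotypeModel:
    """Dosage-effect model for PTA phenotypes.

    ``dosage_effects`` maps ``(locus, trait)`` — with ``locus = (chrom,
    start_bp, end_bp)`` — to the additive effect per copy deviation from 2.
    ``trait_correlation`` is a traits × traits correlation matrix for the
    residuals (defaults to the 4-block structure of the 41-trait catalogue).
    """

    trait_names: tuple[str, ...] = tuple(ALL_TRAITS)
    dosage_effects: Mapping[tuple[tuple[str, int, int], str], float] = field(
        default_factory=dict
    )
    residual_sd: float = 1.0
    trait_correlation: np.ndarray | None = None

    def __post_init__(self):
        if self.residual_sd < 0:
            raise ValueError("residual_sd must be >= 0")
        if self.trait_correlation is not None:
            R = np.asarray(self.trait_correlation)
            if R.shape != (len(self.trait_names),) * 2:
                raise ValueError("trait_correlation shape must match trait_names")
            if not np.allclose(R, R.T):
                raise ValueError("trait_correlation must be symmetric")
            if np.linalg.eigvalsh(R).min() < -1e-8:
                raise ValueError("trait_correlation must be positive semi-definite")

    @property
    def n_traits(self) -> int:
        return len(self.trait_names)


@dataclass(frozen=True)
class TruthSet:
    """Ground truth that fully determines a simulated cohort given its seed."""

    true_cnvs: tuple[TrueCnv, ...]
    true_effects: Mapping[tuple[tuple[str, int, int], str], float]
    seed: int

    def loci(self) -> list[tuple[str, int, int]]:
        seen: dict[tuple[str, int, int], None] = {}
        for cnv in self.true_cnvs:
            seen.setdefault(cnv.locus)
        return list(seen)

    def copy_number(self, sample_id: str, locus: tuple[str, int, int]) -> int:
        """Copy number of ``sample_id`` at ``locus`` (baseline 2 if absent)."""
        for cnv in self.true_cnvs:
            if cnv.sample_id == sample_id and cnv.locus == locus:
                return cnv.copy_number
        return 2


# ---------------------------------------------------------------------------
# seed plumbing
# ---------------------------------------------------------------------------

_STREAMS = ("probes", "cnvs", "signal", "phenotypes", "self_self")


def _rng(seed: int, stream: str) -> np.random.Generator:
    """Named child generator of the master seed."""
    idx = _STREAMS.index(stream)
    children = np.random.SeedSequence(int(seed)).spawn(len(_STREAMS))
    return np.random.default_rng(children[idx])


# ---------------------------------------------------------------------------
# probes
# ---------------------------------------------------------------------------

def simulate_probes(layout: GenomeLayout, seed: int,
                    jitter_frac: float = 0.25) -> pd.DataFrame:
    """Place probes on a near-uniform grid with optional uniform jitter.

    Probes sit at grid centres ``spacing*(i + 0.5)`` jittered by up to
    ``±jitter_frac*spacing`` (jitter_frac < 0.5 preserves order and
    uniqueness).  Returns a DataFrame (probe_id, chrom, pos) sorted by
    (chrom, pos).
    """
    if not 0 <= jitter_frac < 0.5:
        raise ValueError("jitter_frac must be in [0, 0.5)")
    rng = _rng(seed, "probes")
    spacing = layout.probe_spacing_bp
    rows = []
    for chrom, length in layout.chromosomes:
        n = int(length // spacing)
        if n < 1:
            raise ValueError(
                f"probe spacing {spacing} exceeds length of {chrom} ({length} bp)"
            )
        centres = spacing * (np.arange(n) + 0.5)
        if jitter_frac > 0:
            centres = centres + rng.uniform(-jitter_frac, jitter_frac, n) * spacing
        pos = np.clip(np.round(centres).astype(int), 1, length)
        for i, p in enumerate(pos):
            rows.append((f"{chrom}_p{i:06d}", chrom, int(p)))
    return pd.DataFrame(rows, columns=["probe_id", "chrom", "pos"])


# ---------------------------------------------------------------------------
# signal
# ---------------------------------------------------------------------------

def expected_log2(copy_number: int) -> float:
    """Noise-free log2 ratio for an absolute copy number vs a 2-copy reference."""
    if copy_number == 0:
        return CN0_FLOOR_LOG2
    return float(np.log2(copy_number / 2.0))


def simulate_signal(
    probes: pd.DataFrame,
    true_cnvs: Sequence[TrueCnv],
    noise: NoiseModel,
    seed: int,
    *,
    samples: Sequence[str],
    sex_chromosome: str | None = None,
    sample_sex: Mapping[str, str] | None = None,
) -> SignalMatrix:
    """Emit the probe × sample log2-ratio matrix for a truth set.

    Baseline expectation is 0 on autosomes and −1 (one copy vs the 2-copy
    female reference) on ``sex_chromosome`` for male samples.  Probes inside
    a :class:`TrueCnv` take ``log2(cn/2)``.  Gaussian probe noise and a
    per-sample baseline shift are added on top.
    """
    rng = _rng(seed, "signal")
    samples = [str(s) for s in samples]
    known = set(probes["chrom"].astype(str))
    for cnv in true_cnvs:
        if cnv.chrom not in known:
            raise ValueError(f"CNV on unknown chromosome {cnv.chrom!r}")
        if cnv.sample_id not in samples:
            raise ValueError(f"CNV for unknown sample {cnv.sample_id!r}")

    chrom_arr = probes["chrom"].to_numpy(dtype=object)
    pos = probes["pos"].to_numpy()
    n_probes, n_samples = len(probes), len(samples)
    mu = np.zeros((n_probes, n_samples))

    if sex_chromosome is not None:
        on_x = chrom_arr == sex_chromosome
        for j, s in enumerate(samples):
            sex = (sample_sex or {}).get(s, "female")
            if sex == "male":
                mu[on_x, j] = expected_log2(1)

    col = {s: j for j, s in enumerate(samples)}
    for cnv in true_cnvs:
        mask = (chrom_arr == cnv.chrom) & (pos >= cnv.start_bp) & (pos <= cnv.end_bp)
        mu[mask, col[cnv.sample_id]] = expected_log2(cnv.copy_number)

    values = mu
    if noise.probe_sd > 0:
        values = values + rng.normal(0.0, noise.probe_sd, size=mu.shape)
    if noise.sample_shift_sd > 0:
        values = values + rng.normal(0.0, noise.sample_shift_sd, size=(1, n_samples))
    return SignalMatrix(probes=probes.copy(), samples=list(samples), values=values)


def simulate_self_self(probes: pd.DataFrame, noise: NoiseModel, seed: int,
                       n_samples: int = 1) -> SignalMatrix:
    """Noise-only hybridizations of the reference against itself.

    Used to calibrate the false-positive rate of calling: every probe's
    expected value is exactly 0.
    """
    rng = _rng(seed, "self_self")
    shape = (len(probes), n_samples)
    values = np.zeros(shape)
    if noise.probe_sd > 0:
        values = values + rng.normal(0.0, noise.probe_sd, size=shape)
    if noise.sample_shift_sd > 0:
        values = values + rng.normal(0.0, noise.sample_shift_sd, size=(1, n_samples))
    samples = [f"self_self_{i + 1}" for i in range(n_samples)]
    return SignalMatrix(probes=probes.copy(), samples=samples, values=values)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

def block_correlation(sizes: Sequence[int] | None = None,
                      rho: float = 0.6) -> np.ndarray:
    """Block-diagonal correlation matrix (within-block ``rho``, 0 between).

    Defaults to the production/reproduction/health/type block sizes
    (6/9/8/18) of the 41-trait catalogue.
    """
    if sizes is None:
        sizes = [len(v) for v in TRAIT_BLOCKS.values()]
    n = sum(sizes)
    R = np.eye(n)
    off = 0
    for s in sizes:
        R[off:off + s, off:off + s] = rho
        np.fill_diagonal(R[off:off + s, off:off + s], 1.0)
        off += s
    return R


def simulate_phenotypes(samples: Sequence[str], truth: TruthSet,
                        model: PhenotypeModel, seed: int) -> pd.DataFrame:
    """Sample × trait PTA table: dosage effects plus correlated residuals.

    Trait value = Σ_locus effect·(copy_number − 2) + residual, with the
    residual vector drawn from N(0, residual_sd²·R) where R is the trait
    correlation structure.
    """
    rng = _rng(seed, "phenotypes")
    samples = [str(s) for s in samples]
    loci = set(truth.loci())
    for (locus, trait) in model.dosage_effects:
        if locus not in loci:
            raise ValueError(f"effect references locus {locus} absent from truth set")
        if trait not in model.trait_names:
            raise ValueError(f"effect references unknown trait {trait!r}")

    n, t = len(samples), model.n_traits
    genetic = np.zeros((n, t))
    trait_idx = {name: j for j, name in enumerate(model.trait_names)}
    for (locus, trait), effect in model.dosage_effects.items():
        j = trait_idx[trait]
        for i, s in enumerate(samples):
            genetic[i, j] += effect * (truth.copy_number(s, locus) - 2)

    R = model.trait_correlation
    if R is None:
        R = np.eye(t)
    cov = (model.residual_sd ** 2) * np.asarray(R)
    resid = rng.multivariate_normal(np.zeros(t), cov, size=n, method="cholesky") \
        if model.residual_sd > 0 else np.zeros((n, t))
    return pd.DataFrame(genetic + resid, index=pd.Index(samples, name="sample_id"),
                        columns=list(model.trait_names))


def expected_variance_explained(effect: float, dosage_values: Sequence[float],
                                residual_sd: float) -> float:
    """Closed-form fraction of trait variance explained by one locus.

    With dosage deviation D = copy_number − 2, VE = β²Var(D) / (β²Var(D) + σ²).
    """
    var_d = float(np.var(np.asarray(dosage_values, dtype=float) - 2.0))
    num = effect ** 2 * var_d
    denom = num + residual_sd ** 2
    return num / denom if denom > 0 else 0.0


def effect_for_variance_explained(target_ve: float,
                                  dosage_values: Sequence[float],
                                  residual_sd: float) -> float:
    """Effect size β making one locus explain ``target_ve`` of trait variance."""
    if not 0 < target_ve < 1:
        raise ValueError("target_ve must be in (0, 1)")
    var_d = float(np.var(np.asarray(dosage_values, dtype=float) - 2.0))
    if var_d <= 0:
        raise ValueError("dosage values are constant; no variance to explain")
    return residual_sd * np.sqrt(target_ve / (1.0 - target_ve) / var_d)


# ---------------------------------------------------------------------------
# cohort planting
# ---------------------------------------------------------------------------

def plant_cohort_cnvs(
    probes: pd.DataFrame,
    samples: Sequence[str],
    seed: int,
    *,
    n_loci: int = 30,
    probes_per_locus: tuple[int, int] = (5, 40),
    carrier_freq: tuple[float, float] = (0.1, 0.5),
    copy_states: tuple[int, ...] = (1, 3),
    chromosomes: Sequence[str] | None = None,
    min_gap_probes: int = 5,
) -> list[TrueCnv]:
    """Plant non-overlapping CNV loci and assign carriers.

    Each locus spans a contiguous probe window (so its bp boundaries are the
    first/last member probe positions); carriers are drawn per locus at a
    frequency uniform in ``carrier_freq`` and all carriers at a locus share
    one non-diploid copy state from ``copy_states``.
    """
    rng = _rng(seed, "cnvs")
    samples = [str(s) for s in samples]
    chroms = list(chromosomes) if chromosomes is not None else sorted(
        set(probes["chrom"].astype(str))
    )
    by_chrom = {
        c: probes.index[probes["chrom"] == c].to_numpy() for c in chroms
    }
    pos = probes["pos"].to_numpy()

    used: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    events: list[TrueCnv] = []
    weights = np.array([len(by_chrom[c]) for c in chroms], dtype=float)
    weights = weights / weights.sum()
    placed = 0
    attempts = 0
    while placed < n_loci and attempts < 200 * n_loci:
        attempts += 1
        chrom = rng.choice(chroms, p=weights)
        idx = by_chrom[chrom]
        span = int(rng.integers(probes_per_locus[0], probes_per_locus[1] + 1))
        if len(idx) <= span + 2 * min_gap_probes:
            continue
        first = int(rng.integers(0, len(idx) - span))
        last = first + span - 1
        clash = any(
            first <= b + min_gap_probes and last >= a - min_gap_probes
            for a, b in used[chrom]
        )
        if clash:
            continue
        used[chrom].append((first, last))
        start_bp = int(pos[idx[first]])
        end_bp = int(pos[idx[last]])
        freq = rng.uniform(*carrier_freq)
        cn = int(rng.choice(copy_states))
        carriers = [s for s in samples if rng.uniform() < freq]
        if not carriers:
            carriers = [samples[int(rng.integers(0, len(samples)))]]
        for s in carriers:
            events.append(TrueCnv(s, chrom, start_bp, end_bp, cn))
        placed += 1
    if placed < n_loci:
        raise RuntimeError(
            f"could only place {placed}/{n_loci} loci; genome too small"
        )
    events.sort(key=lambda e: (e.chrom, e.start_bp, e.sample_id))
    return events
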