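"""Simulate a small aCGH cohort with known CNV truth.

Builds a two-chromosome genome with 1.2 kb probe spacing, plants 8 CNV loci
across 47 samples, and emits the probe x sample log2-ratio matrix plus
block-correlated PTA phenotypes carrying one dosage effect.
"""

import numpy as np

import arraycnv as ac

layout = ac.GenomeLayout((("chr1", 600_000), ("chr2", 600_000)),
                         probe_spacing_bp=1200.0)
probes = ac.simulate_probes(layout, seed=1)
chr1_pos = probes.loc[probes["chrom"] == "chr1", "pos"].to_numpy()
print(f"{len(probes)} probes, mean chr1 spacing "
      f"{np.diff(chr1_pos).mean():.0f} bp")

samples = [f"S{i + 1:02d}" for i in range(47)]
cnvs = ac.plant_cohort_cnvs(probes, samples, seed=1, n_loci=8)
truth = ac.TruthSet(tuple(cnvs), {}, seed=1)
print(f"{len(truth.loci())} planted loci, {len(cnvs)} sample-level events")

sm = ac.simulate_signal(probes, cnvs, ac.NoiseModel(probe_sd=0.15), seed=1,
                        samples=samples)
inside = sm.values[:, 0][
    (probes["chrom"] == cnvs[0].chrom).to_numpy()
    & (probes["pos"].to_numpy() >= cnvs[0].start_bp)
    & (probes["pos"].to_numpy() <= cnvs[0].end_bp)
]
print(f"first event: {cnvs[0].chrom}:{cnvs[0].start_bp}-{cnvs[0].end_bp} "
      f"cn={cnvs[0].copy_number} in {cnvs[0].sample_id}")

# a dosage effect designed to explain 20% of one trait's variance
locus = truth.loci()[0]
dosages = [truth.copy_number(s, locus) for s in samples]
beta = ac.effect_for_variance_explained(0.20, dosages, residual_sd=1.0)
model = ac.PhenotypeModel(trait_names=("Dtr_Preg_Rate", "Milk"),
                          dosage_effects={(locus, "Dtr_Preg_Rate"): beta},
                          residual_sd=1.0)
traits = ac.simulate_phenotypes(samples, ac.TruthSet(tuple(cnvs),
                                                     model.dosage_effects, 1),
                                model, seed=1)
print(f"effect size beta={beta:.3f} PTA units per copy "
      f"(designed to explain 20% of Dtr_Preg_Rate variance)")
print(f"trait table: {traits.shape[0]} samples x {traits.shape[1]} traits")
# Every number above is reproducible: the same seed regenerates the cohort
# byte for byte.
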