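#!/usr/bin/env python
"""Generate the synthetic study assemblages used by the downstream analyses.

Writes to results/data/:
  mg_table.tsv        — fine-grained (MG-level) neutral assemblage with
                        within-function competitive turnover planted
  annotation.tsv      — redundant MG -> function map (10 members/function)
  healthy.tsv / diseased.tsv — treatment pair with a planted fold change
  cp_table.tsv        — latent-factor table with a planted core/periphery
  truth_*.tsv         — ground-truth labels for each planted structure
"""

from pathlib import Path

from omuecol.simulate import (
    SyntheticSpec,
    plant_core_periphery,
    plant_functional_turnover,
    plant_treatment_effect,
    redundant_annotation,
    sample_source_profile,
    simulate_neutral_assemblage,
)

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results" / "data"
OUT.mkdir(parents=True, exist_ok=True)


def main() -> None:
    # fine-grained assemblage: 300 gene-level OMUs, 50 samples
    spec = SyntheticSpec(n_omu=300, n_samples=50, I_T=10_000, m=0.3,
                         depth=10_000, seed=SEED)
    profile = sample_source_profile(spec)
    mg, _ = simulate_neutral_assemblage(profile, spec.m, spec.I_T,
                                        spec.n_samples, spec.depth,
                                        seed=SEED + 1, level="MG")
    ann = redundant_annotation(mg.omu_ids, n_functions=30,
                               multi_label_rate=0.2, seed=SEED + 2)
    mg = plant_functional_turnover(mg, ann, switching=0.2, seed=SEED + 3)
    mg.to_tsv(OUT / "mg_table.tsv")
    ann.to_tsv(OUT / "annotation.tsv")

    # treatment pair at the functional-cluster scale
    spec2 = SyntheticSpec(n_omu=200, n_samples=30, I_T=10_000, m=0.3,
                          depth=10_000, seed=SEED + 10)
    prof2 = sample_source_profile(spec2)
    base, _ = simulate_neutral_assemblage(prof2, spec2.m, spec2.I_T,
                                          spec2.n_samples, spec2.depth,
                                          seed=SEED + 11)
    affected = list(base.omu_ids)[:20]
    healthy, diseased, truth = plant_treatment_effect(base, affected,
                                                      fold=8.0, seed=SEED + 12)
    healthy.to_tsv(OUT / "healthy.tsv")
    diseased.to_tsv(OUT / "diseased.tsv")
    truth.to_frame().to_csv(OUT / "truth_treatment.tsv", sep="\t", index=False)

    # planted core/periphery correlation structure
    cp, cp_truth = plant_core_periphery(8, 24, 100, loading=0.9, noise=1.0,
                                        seed=SEED + 20)
    cp.to_tsv(OUT / "cp_table.tsv")
    cp_truth.to_frame().to_csv(OUT / "truth_core_periphery.tsv", sep="\t",
                               index=False)

    print(f"wrote synthetic assemblages to {OUT}")
    print(f"  MG table: {mg.n_omu} OMUs x {mg.n_samples} samples, "
          f"{len(ann.labels)} functions")
    print(f"  treatment pair: {healthy.n_omu} OMUs, {healthy.n_samples}+"
          f"{diseased.n_samples} samples, {len(affected)} affected OMUs")
    print(f"  core/periphery table: {cp.n_omu} OMUs "
          f"({sum(1 for v in cp_truth.structure.values() if v == 'core')} core)")


if __name__ == "__main__":
    main()
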