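"""Generate the synthetic study cohort.

Draws one cohort under the default study conditions -- 300 samples, 10 CNV
driver genes (alternating high-level amplification / homozygous deletion in
15% of samples, 1.5 log2-units expression dose effect), 20 planted weakened
ceRNA pairs (miRNA coupling 0.8 attenuated to 0.16 in carrier samples), plus
background ceRNA structure with no CNV dependence -- and writes every
pipeline input plus the ground truth.
"""

from common import COHORT_DIR, SEED

from cnvcerna.simulate import SimulationConfig, generate_cohort, write_cohort


def main() -> None:
    cfg = SimulationConfig(seed=SEED)
    cohort = generate_cohort(cfg)
    paths = write_cohort(cohort, COHORT_DIR)
    t = cohort.truth
    print(f"cohort written to {COHORT_DIR}")
    print(f"  samples: {cfg.n_samples}, mRNA: {cfg.n_mrna}, "
          f"lncRNA: {cfg.n_lncrna}, miRNA: {cfg.n_mirna}")
    print(f"  planted drivers: {len(t.planted_drivers)} "
          f"({sum(d['direction'] == 'amplification' for d in t.planted_drivers)} amp / "
          f"{sum(d['direction'] == 'deletion' for d in t.planted_drivers)} del)")
    print(f"  planted weakened pairs: {len(t.planted_pairs)}; "
          f"null shared-miRNA pairs: {len(t.null_pairs)}")
    print(f"  files: {', '.join(p.name for p in paths.values())}")


if __name__ == "__main__":
    main()
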