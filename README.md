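# cnvcerna

Discovery of competing-endogenous-RNA (ceRNA) interactions whose strength is
altered by DNA copy-number variation (CNV), for cancer-genomics analyses that
combine discrete gene-level copy-number calls (GISTIC-style, −2…2) with mRNA,
lncRNA and miRNA expression matrices.

Two RNAs sharing miRNA binding sites compete for the shared miRNA and are
positively co-expressed; a copy-number event can decouple (or tighten) that
crosstalk in carrier samples. The pipeline:

1. **CNV-driven genes** — clean the calls (recode ±1 to neutral, drop
   non-recurrent genes, resolve mixed +2/−2 states with an exact binomial
   noise test), then call a gene CNV-driven when a two-sided rank-sum test
   between aberrant and copy-neutral samples gives *P* < 0.05 with a
   concordant median shift.
2. **Candidate triplets** — within each copy-number status, screen every
   expressed RNA pair sharing a miRNA for the ceRNA signature: pair Pearson
   r > 0 and both miRNA–target r < 0, each at BH-adjusted *q* < 0.05.
3. **Dysregulation** — score each pair with ΔR = |cor_v − cor_n| (its
   correlation in aberrant vs neutral samples) and test it by permuting the
   status labels 1000 times; pairs with permutation *p* < 0.05 are
   *enhanced* (cor_v > cor_n) or *weakened* by the CNV.
4. **Network analysis & clinic** — assemble the dysregulated ceRNA network,
   detect communities by multilevel modularity optimisation, test
   hypergeometric gene-set enrichment, and associate drivers with overall
   survival (Kaplan–Meier / log-rank, Cox) and histological subtype (exact
   r×c Fisher test).

Because such tumor-cohort inputs cannot ship with the code, the package
includes a first-class synthetic-cohort generator (`cnvcerna.simulate`) that
realises exactly this structure with planted ground truth, so every stage is
testable end to end. See `docs/methods.md` for the model, defaults and
limitations.

## Worked example

The numbered scripts under `analysis/` run the whole study on a synthetic
cohort (300 samples; 10 planted CNV drivers; 20 planted weakened ceRNA
pairs; background ceRNA structure with no CNV dependence). Data are written
under `scratch/`, result tables under `results/analysis/`:

```bash
cd analysis
python 01_simulate_cohort.py
python 02_find_cnv_drivers.py
python 03_screen_triplets.py
python 04_test_dysregulation.py
python 05_network_communities.py
python 06_enrichment.py
python 07_clinical_association.py
```

Output of the driver and dysregulation stages:

```
11 (gene, direction) units tested; 10 called CNV-driven at P < 0.05 with concordance
planted-driver recall: 100% (10/10)

127 significant dysregulated pairs of 2570 tested
per driver state:
direction      enhanced  weakened
driver_state
amplification        10        45
deletion             16        56
planted-pair recall: 20/20; direction correct for 20/20 recovered
```

All 10 planted drivers are recovered; all 20 planted weakened pairs are
found with the correct direction. The ~107 additional significant pairs are
the expected 5% type-I yield of testing ~2550 null pair-driver combinations
at the raw *p* < 0.05 cut-off the method prescribes — on real data this is
the price of the published threshold choice. The clinical stage flags the
one driver whose deletion the generator tied to survival and subtype
(log-rank *p* = 2.6e−06, carrier hazard ratio 2.30, subtype Fisher
*p* = 5.2e−05).

The same stages are available as a CLI (`cnvcerna simulate | drivers |
triplets | dysregulate | network | enrich | clinical | fisher | run-all`);
`run-all` executes everything from one YAML config and writes a manifest
with per-stage counts.

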