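# shdelim — cross-checking DNA-barcode species hypotheses

Molecular taxonomists routinely delimit species from a single barcode locus
(for fungi, the ITS region) and then have to reconcile the fact that every
delimitation method draws the lines differently. `shdelim` implements the
cross-check workflow used in modern barcode taxonomy: run several independent
delimitation models over the same sequences, lay their species hypotheses
(SHs) side by side, and accept a candidate species only when a **majority of
methods** (> 4 of 7 by default) return it as an exact cluster.

It is aimed at systematists and barcoding studies that want a reproducible,
scriptable version of this cross-check, without web servers and with every
knob recorded.

## The methods

All engines reduce to a `Partition` — a map from sequence id to SH — over the
same sequence set:

| engine | input | model |
|---|---|---|
| `otu.greedy_cluster` | sequences | greedy centroid clustering at identity threshold t (0.97, 0.985): a query joins the best-matching centroid with identity ≥ t, else founds a new one |
| `asap.asap_partitions` | distance matrix | nested single-linkage partitions scored by a composite of a panmixia probability p and relative barcode-gap width W = (d₊ − d)/d₊; lowest mean rank wins |
| `gmyc.gmyc_fit` | ultrametric tree | single-threshold GMYC: log L = Σᵢ (ln bᵢ − bᵢxᵢ) with bᵢ = λ_spec·kᵢ + λ_coal·Σⱼ nᵢⱼ(nᵢⱼ−1); threshold profiled over branching-time midpoints, LR test vs the one-process null |
| `ptp.ptp_ml` / `ptp_bayes` | phylogram | PTP: two iid exponential branch-length classes split by an antichain of species roots; ML by restarted hill climbing, Bayesian by MCMC with per-species support; the fewer-SH result is adopted |
| `seqio.read_partition_table` | TSV | externally computed SH assignments (e.g. reference-database SH codes) ingested as first-class methods |

Distances are p-distance or Jukes–Cantor, d = −(3/4)·ln(1 − 4p/3), with
pairwise deletion. `consensus.assemble` builds the per-sequence comparison
table, `consensus.majority_decision` applies the strict majority rule, and
`consensus.run_pipeline` drives everything end to end.

A seeded generator (`simulate`) produces barcode datasets with known species:
Yule species tree → multispecies coalescent (msprime) → Jukes–Cantor sequence
evolution, so the entire pipeline is testable against ground truth with no
downloads. See `docs/methods.md` for models, parameter defaults and known
limitations (notably: PTP oversplits species with deep within-species
coalescent structure, and the GMYC LR p-value is anticonservative — the
consensus is the mitigation for both).

## Worked example

The numbered scripts under `analysis/` run the whole study on a simulated
5-species × 8-sequence dataset (500 bp, strong barcode gap) and write their
tables under `results/`:

```
$ python analysis/01_simulate_dataset.py
wrote 40 sequences (5 species) to data/
barcode gap: max within 0.0040 << min between 0.0824

$ python analysis/02_delimit.py
SH counts: {'SH-3%': 5, 'SH-1.5%': 5, 'OTU-97': 5, 'OTU-98.5': 5, 'ASAP': 5, 'GMYC': 5, 'PTP': 6}
GMYC threshold 0.5169, LR 147.8, p 8.15e-33
PTP: ML 6 vs Bayesian 6 SHs; adopted the fewer

$ python analysis/03_consensus.py
5/5 candidate species accepted (support > 4 of 7 methods)
  sp1: support 7/7 -> accepted
  ...
  sp5: support 6/7 -> accepted
```

Reading: the within-species JC distances top out at 0.004 while between-species
distances start at 0.082 — a clean barcode gap — so six of the seven methods
return exactly the five true species. PTP splits one species in two (its
branch-length model reads the deepest within-species coalescence as a
speciation event), so that species' support drops to 6 of 7, still accepted.
`analysis/04_recovery_study.py` repeats this over 25 independent datasets and
tabulates how often each engine recovers the truth.

The same machinery is available as a CLI for real data:

```bash
shdelim simulate --seed 1 --out demo/
shdelim cluster --fasta demo/sequences.fasta --threshold 0.97 --out otu.tsv
shdelim gmyc --tree demo/gene_tree_ultrametric.nwk --out gmyc.tsv
shdelim ptp --tree demo/phylogram.nwk --mode both --seed 42 --out ptp.tsv
shdelim run --config pipeline.json
```

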