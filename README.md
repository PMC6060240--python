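# microdiv

Comparative microdiversity genomics for sets of closely related bacterial
strains — the within-species regime (ANI ≥ 98%) where homologous
recombination (HR), not mutation, can dominate how core genomes diversify,
and where the accessory genome turns over through island hotspots and
plasmids.

Given complete genomes (or a whole-genome alignment), the toolkit computes:

* **Genome identity** — pairwise ANIb from fragment tables (built-in
  anchored matcher or parsed MUMmer `show-coords` output): fragments
  contained in a larger fragment are dropped, fragments overlapping by more
  than 10% of the shorter are joined, and ANIb is the length-weighted mean
  identity. Alignment-free TETRA correlations of strand-symmetrized
  tetranucleotide z-scores complement it.
* **Pangenome structure** — core/accessory partition of a gene-family
  presence/absence matrix, gene-accumulation curves over random strain
  orders, and a sliding-window scan for accessory-dense genomic islands.
* **Recombination detection** — an ensemble of three scanning statistics
  on the core alignment (MaxChi, a Chimaera-style triplet scan, an
  RDP-style window scan), combined by k-of-m consensus at p < 0.001 with
  permutation/binomial significance; tracts and recipient strains are
  delineated by divergence profiling inside the certified regions, with
  MaxChi breakpoint refinement and donor inference.
* **Recombination impact** — a recombination-masked neighbor-joining
  clonal genealogy; direct-count estimates of r/m (substitutions imported
  by HR per clonal mutation) and rho/theta (HR events per mutation);
  single-linkage clonal-frame clustering of the ANIb matrix.
* **Selection and function** — pairwise dN/dS by Nei–Gojobori counting
  with Jukes–Cantor correction, and Fisher-exact COG-category enrichment of
  recombined regions versus the genome background with Benjamini–Hochberg
  FDR.
* **A truth-tracked simulator** — recombining populations with a known
  clonal genealogy, Poisson mutations, geometric-length imports from a
  divergent donor pool with exactly counted imported substitutions, and
  hotspot-structured accessory gain, so every stage can be validated
  against ground truth.

## Worked example

```python
from microdiv import (SimParams, simulate_population, ani_matrix,
                      extract_variable_sites, scan_all, ensemble_consensus,
                      estimate_rates)

genomes, truth, matrix, blocks = simulate_population(SimParams(seed=1))
ani, _ = ani_matrix(genomes[:2])
print(f"ANIb(S01,S02) = {ani.iloc[0, 1]:.2f}")

strains = sorted(g.strain_id for g in genomes)
cols = extract_variable_sites(blocks, strains)
events = ensemble_consensus(cols, scan_all(cols, seed=1))
est = estimate_rates(cols, events)
print(f"{len(events)} events (truth: {len(truth.recomb_tracts)} tracts)")
print(f"rho/theta = {est.rho_over_theta:.3f} "
      f"(realized: {truth.realized_rho_over_theta:.3f})")
```

prints

```
ANIb(S01,S02) = 99.99
28 events (truth: 41 tracts)
rho/theta = 0.233 (realized: 0.328)
```

ANIb sits well inside the species range; the detector recovers most of the
41 true imports (overlapping tracts merge into single events, hence the
lower count) and the event-per-mutation ratio lands near the simulated
rho/theta of 0.3.

The same stages are available from a shell:

```bash
microdiv --seed 1 simulate --outdir sim
microdiv ani sim/S0*.fa --out ani.tsv
microdiv --seed 1 recombination --xmfa sim/core_alignment.xmfa --outdir rec
microdiv popgen --xmfa sim/core_alignment.xmfa --events rec/events.tsv \
    --outdir pop --ani-matrix ani.tsv
microdiv enrich --genes sim/S01_genes.tsv --events rec/events.tsv --out enr.tsv
```

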