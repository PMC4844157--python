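# famscan

Genome-wide gene-family characterization for hexaploid-style plant
genomes, built around the workflow used to survey lectin receptor kinase
(LRK) families in bread wheat: identify family members by domain
architecture, cluster homologs across the A/B/D sub-genomes and name them,
call tandem and segmental duplications, find orthologs in a sister
species, build neighbor-joining phylogenies with bootstrap supports, and
profile RPKM expression across organs, developmental stages and stress
conditions.

## Who it is for

Researchers running receptor-kinase-style family surveys who want the
whole analysis chain as a reusable, deterministic, tested library instead
of a pile of one-off scripts — and who want every rule validated against
a genome where the right answer is planted and known.

## The rules at the core

* **Family class.** A gene is an LRK iff its protein has a Ser/Thr
  protein-kinase domain plus an extracellular lectin domain; the lectin
  type sets the class (legume → L-LRK, bulb/GNA → B-LRK, Ca-dependent →
  C-LRK).  S-locus glycoprotein and PAN/APPLE hits are accessory.
* **Homologs.** Single-linkage clusters over pairs with identity > 90%
  at E ≤ 10⁻¹⁰ (Karlin–Altschul E = K·m·n·e^(−λS) over affine-gap
  Smith–Waterman with BLOSUM62, gap −11/−1).  One member per cluster is
  the named gene (`L-LRK13`), the rest its homologs (`L-LRK13.2`).
* **Duplications.** Same-chromosome pairs at identity ≥ 80%: tandem (TD)
  within 5 Mb, segmental (SD) beyond; scaffold-located members leave the
  event uncategorized.
* **Orthologs.** Best bidirectional hit at E ≤ 10⁻¹⁰.
* **Phylogeny.** Center-star MSA → p-distances (pairwise deletion) →
  Saitou–Nei NJ → column-resampling bootstrap (default 1000 replicates).
* **Expression.** RPKM = count·10⁹/(length·library total) from
  exact-substring read mapping (100% coverage and identity, both
  strands); stress responses flagged at ≥ 2-fold up or ≤ 0.5-fold down
  on replicate-averaged RPKM.

A synthetic-study generator (`famscan.synthetic_data`) emits a miniature
two-species hexaploid-style dataset — homoeolog triplets, planted
duplications, orthologs, decoys, and condition-structured reads with
planted fold changes — together with machine-readable ground truth for
every layer.

## Worked example

```python
from famscan.synthetic_data import SimConfig, simulate
from famscan.domains import load_packaged_models, classify_proteins
from famscan.align import all_vs_all
from famscan.homology import cluster_homologs, assign_nomenclature, find_duplications

study = simulate(SimConfig(seed=7, n_families=8, family_mix=(4, 3, 1),
                           n_tandem=1, n_segmental=1, n_scaffold_dups=1,
                           n_decoys=4, reads_per_sample=3000))
proteins = study.genome_a.proteins()

classes = classify_proteins(proteins, load_packaged_models())
n_lrk = sum(a.family != "none" for a in classes.values())
print(f"{n_lrk} LRK genes among {len(proteins)} gene models")

hits = all_vs_all(proteins)
lrk_l = [g for g, a in classes.items() if a.family == "L_LRK"]
clusters = assign_nomenclature(
    cluster_homologs(hits, lrk_l, family="L_LRK"), "L-LRK", proteins)
for c in clusters[:3]:
    print(f"cluster {c.cluster_id}: {', '.join(sorted(c.names.values()))}")

for e in find_duplications(study.genome_a, hits):
    print(f"{e.gene_a} x {e.gene_b}: {e.category} ({e.identity_pct:.1f}% identity)")
```

prints

```
27 LRK genes among 31 gene models
cluster 1: L-LRK1, L-LRK1.1, L-LRK1.2, L-LRK1.3
cluster 2: L-LRK2, L-LRK2.1, L-LRK2.2
cluster 3: L-LRK3, L-LRK3.1, L-LRK3.2
Traes_1AS_0001 x Traes_1AS_0004: TD (95.1% identity)
Traes_4AS_0011 x scaffold_1001_g1: uncategorized (82.6% identity)
Traes_7AL_0023 x Traes_7AS_0020: SD (84.7% identity)
```

The 31 gene models are 8 families × 3 homoeologs plus three duplicate
copies and four negative-control decoys; the decoys are the four genes
classified outside the family, every homoeolog triplet lands in one
cluster, and the three planted duplications come back with their planted
TD/SD/uncategorized labels and identities.

## Command line

```bash
famscan run --out outdir --seed 7        # full workflow on the synthetic study
famscan simulate --seed 7 --out sim/     # just the data + ground truth
famscan allvsall --in prot.fa --out hits.tsv
famscan phylo --in family.fa --reps 1000 --seed 7 --out tree.nwk
famscan express --reads sim/reads --samples sim/samples.tsv \
                --transcripts sim/speciesA.cds.fa --out expr/
famscan stage homology --out outdir      # re-run one stage in place
```

`famscan run` writes per-stage directories (`sim/`, `ingest/`, `align/`,
`classify/`, `homology/`, `phylo/`, `express/`, `report/`); every TSV
carries a provenance header (version, seed, thresholds) and re-running
with the same seed reproduces all outputs byte-for-byte.

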