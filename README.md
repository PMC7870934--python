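# tcmis

Systems-pharmacology screening of herb-derived natural products for a
disease indication. The pipeline:

1. **Literature screen** (`litmine`) — per-herb paper counts against corpus
   constants; hypergeometric upper-tail p-values, BH adjustment, and the
   q < 0.01 / ratio > 0.05 significance rule.
2. **Network assembly** (`hct_network`) — tripartite herb–compound–target
   graph; compound–target edges classified *direct* (Ki/Kd/IC50/EC50
   < 10 μM) or *indirect*, deduped direct-over-indirect; gene-set
   restriction, degree analysis (K per compound, D per target), high-degree
   gene selection, single-herb subnetworks, shared targets, and per-herb
   positive-ingredient proportions.
3. **Gene-set curation** (`genesets`) — Entrez-ID sets from GMT or
   one-ID-per-line files; agent-count filtering, ≥2-of-3 integration
   (IG-1), union (IG-2), and pairwise overlap enrichment.
4. **Scoring models** (`permscore`) — per gene set, a shared bank of
   100,000 random gene-set draws from the 20,462-gene universe yields a
   strict-tail permutation p-value and z-score for each compound's member
   target count; BH across compounds, positives at q < 0.01; an exact
   analytic fast path (hypergeometric strict tail + closed-form moments)
   is available for validation and bit-stable runs. Five models combine
   into a consensus ranking by averaged normalized z-scores.
5. **Scaffold clustering** (`chemclust`) — feature-class circular
   fingerprints (radius 3, 2048 bits, RDKit), Tanimoto distance, and
   k-medoids with RMS-distance medoid centers.
6. **Synthetic data** (`synthetic`) — seeded generators for every input
   table with planted ground truth (enriched herbs, member-biased
   compounds, fingerprint prototypes).

Core statistics (`stats_core`) are shared: log-space-stable hypergeometric
tails, BH step-up, set-overlap enrichment.

## CLI

```sh
# generate synthetic inputs with known ground truth
tcmis synth all --seed 17 --out data/synth

# individual stages
tcmis screen --input data/synth/literature.tsv --out screened.tsv
tcmis network --herb-compound data/synth/herb_compound.tsv \
    --compound-target data/synth/compound_target.tsv \
    --gmt data/synth/genesets.gmt --out netdir
tcmis score --compound-target data/synth/compound_target.tsv \
    --gmt data/synth/genesets.gmt --roster IO,IM,IN,IG-1,IG-2 \
    --permutations 100000 --seed 17 --out scoredir
tcmis cluster --smiles data/synth/smiles.tsv --k 5 --seed 17 --out clustdir
tcmis case-study --herb-compound ... --compound-target ... --gmt ... \
    --herb herb0001 --compounds cmpd0001,cmpd0002 --out casedir

# everything from one YAML config, with a manifest of stage counts
tcmis run --config run.yaml --out rundir
```

`run.yaml` schema (all thresholds shown at their defaults):

```yaml
inputs:
  literature: data/synth/literature.tsv
  herb_compound: data/synth/herb_compound.tsv
  compound_target: data/synth/compound_target.tsv
  genesets_gmt: data/synth/genesets.gmt
  smiles: data/synth/smiles.tsv
  blocklist: null            # optional ion/solvent compound ids
corpus: {total_papers: 29000000, disease_papers: 3874763}
thresholds:
  q_herb: 0.01
  r: 0.05
  affinity_um: 10.0
  q_compound: 0.01
  min_degree: 10
  proportion: 0.10
permutations: 100000
universe: 20462
seed: 17
roster: [IO, IM, IN, IG-1, IG-2]
method: permutation          # or "analytic"
normalization: zstandardize  # or "minmax"
clusters: 5
case_study: {herb: herb0001, compounds: [cmpd0001, cmpd0002]}
```

Outputs are plain TSV/GraphML/JSON; every TSV carries a header comment
with the config hash and seed, and `manifest.json` records row counts at
every stage.

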