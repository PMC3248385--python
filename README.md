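# correlognet

Infer direct gene–gene co-occurrence associations from binary phylogenetic
profiles (gene × species presence/absence matrices), separate them into
positively coupled pairs ("correlogs") and mutually exclusive pairs
("anti-correlogs"), extract the maximum relatedness subnetwork (MRS)
backbone, decompose it into correlog groups, and run the accompanying
statistical analyses.

## Method overview

1. **Filtering** — genes are kept when their balance
   `X_i = min(E_i, N − E_i)` (presence count vs absence count) reaches a
   threshold (`--x-th`, default 80), removing profiles too rare or too
   ubiquitous to carry signal.
2. **Association** — Pearson correlation of the 0/1 profiles is regularized
   toward the identity with the analytic Ledoit–Wolf / Schäfer–Strimmer
   shrinkage intensity λ, and the partial correlation `w` is computed from
   the precision matrix of the shrunk correlation. This removes transitive
   (indirect) correlations; `w > 0` marks correlogy, `w < 0` anti-correlogy.
   Mutual information is provided for comparison.
3. **Backbone** — in the MRS every gene points to its single strongest
   positive and single strongest negative partner. Connected components of
   the undirected positive edges are the correlog groups; negative edges
   typically bridge distinct groups.
4. **Statistics** — exact mean/variance of the number of distinct groups hit
   by a random gene set (clustering Z for organisms or environmental
   samples), functional-coherence and category-overlap permutation tests,
   pair-set weight comparisons stratified by interaction-network distance,
   and a surrogate-based Z for the coupling-strength vs phylum-spread slope.
5. **Synthetic data** — a planted-module generator (modules, mutually
   exclusive module pairs, noise) emits profiles, annotations, taxonomies,
   interaction graphs and organism gene sets in the exact formats the
   pipeline consumes, so everything is testable offline.

## CLI

```sh
# make a synthetic fixture bundle
correlognet simulate --seed 1 --out-dir sim/

# profiles -> association edge list (r, r*, w, I) + filter report
correlognet infer --profile sim/profiles.tsv --x-th 30 --out-dir run/

# edge list -> MRS backbone, correlog groups, coupling strengths, GraphML
correlognet mrs --edges run/edges.tsv --out-dir run/

# analyses
correlognet stats cluster  --groups run/groups.tsv --gene-set sim/gene_sets/organism_00.txt --out-dir run/
correlognet stats coherence --groups run/groups.tsv --annotations sim/annotations.tsv --out-dir run/
correlognet stats overlap  --groups run/groups.tsv --annotations sim/annotations.tsv --c1 C00 --c2 C01 --out-dir run/
correlognet stats pairset  --edges run/edges.tsv --pairs sim/interactions.tsv --graph sim/interactions.tsv --out-dir run/
correlognet stats phylum   --profile sim/profiles.tsv --taxonomy sim/taxonomy.tsv --x-th 30 --n-phyla-max 13 --out-dir run/
```

The phylum-dispersion regression defaults to genes present in fewer than 7
phyla (`--n-phyla-max 7`, the unsaturated regime); the synthetic bundle's
genes are all broadly distributed, hence the wider window above.

Every run writes a `metadata.json` with the package version, effective
parameters, seeds, and SHA-256 hashes of its inputs. Validation failures
exit with status 2.

### File formats (all TSV / plain text)

- profile matrix: header `gene<TAB>sp1<TAB>sp2…`, cells `0`/`1`; or a
  two-column `gene<TAB>species` occurrence list (`--dialect pairs`)
- annotations: `gene<TAB>category`, one row per label (multi-label allowed)
- taxonomy: `species<TAB>phylum`
- interaction graph / designated pairs: `gene_a<TAB>gene_b`
- gene sets: one gene id per line, one file per organism/sample

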