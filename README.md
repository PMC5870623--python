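# domctx

Order-aware, probabilistic context scoring for protein domain prediction.

`domctx` post-processes permissively thresholded profile-HMM hits (HMMER3
`hmmscan --domtblout` tables). Each candidate contributes its bit score
relative to its family's curated domain threshold, and every *ordered* pair
of candidates contributes a directional log2-odds context score estimated
from a directed family-pair count network with symmetric-Dirichlet
smoothing. Per protein, the exact highest-scoring conflict-free subset is
selected by positive-elimination pruning, a provably sound trivial-solution
shortcut, and an integer linear program (tight three-constraint AND
linearisation for pair variables, greedy clique cover for conflicts).

Key properties:

- **Directional**: `S(A before B)` generally differs from `S(B after A)`;
  all ordered pairs are scored, not just adjacent ones.
- **Probabilistic**: unobserved family pairs share a fixed negative
  penalty `log2(alpha * n^2 / (C + alpha * n^2))`, so unlikely
  combinations are actively discouraged.
- **Exact**: the returned subset provably maximises the objective; a
  brute-force enumerator ships as an independent test oracle.

## CLI

Four subcommands: `run`, `net`, `fdr`, `sim`.

```sh
# generate a fully synthetic input set from a seed
domctx sim --seed 7 --proteins 5 --out-prefix sim

# select optimal domain subsets per protein
domctx run --hits sim.domtblout --meta sim.meta.tsv \
           --counts sim.counts.tsv --out predictions.tsv

# build a directed family-pair count network from architectures
domctx net --arch architectures.tsv --out counts.tsv

# macro-averaged FDR from labeled predictions (TP/FP per protein)
domctx fdr --labels labels.tsv --mode revseq
```

Defaults mirror standard practice: `--overlap-aa 40 --overlap-frac 0.5
--alpha 1e-3 --pvalue 1e-4`. Two candidates conflict when they overlap by
more than 40 residues or more than half of the shorter of the two ranges
(envelope coordinates by default, `--overlap-coords ali` to switch);
curated nesting partners are exempt.

The expected upstream search is:

```sh
hmmscan --domtblout hits.txt --F1 1e-1 --F2 1e-1 --F3 1e-2 \
        -Z 1 --domZ 1 -E 1e-4 --domE 1e-4 Pfam-A.hmm query.fa
```

`-Z 1 --domZ 1` makes the E-value columns hold P-values, which the loader
expects; pass `--search-space Z` to `domctx run` if you ran without them.

### Input formats

- **Hits**: HMMER3 `--domtblout` (hmmscan orientation: target = family HMM,
  query = protein).
- **Family metadata** (TSV): `family_id  t_seq  t_dom  clan_id  nesting`,
  where `nesting` is a semicolon-joined whitelist of families allowed to
  overlap without conflict. The per-family surplus `t_seq - t_dom` is
  charged once per predicted family; it is ignored when
  `t_dom >= 0.9 * t_seq`.
- **Counts** (TSV): `family_i  family_j  count` — directed, self-pairs
  allowed; counts of exactly 1 are dropped at load time as presumed noise.
- **Architectures** (TSV, for `net`): `protein_id<TAB>fam1,fam2,...`
  ordered by start coordinate.

## Library

```python
from domctx import estimate_scores, predict, brute_force

model = estimate_scores(counts, families, alpha=1e-3)
solution = predict(candidates, meta, model)      # exact optimum
oracle = brute_force(candidates, meta, model)    # independent check, k <= 20
assert abs(solution.objective - oracle.objective) < 1e-6
```

Modules map one-to-one onto the pipeline: `io_formats` (parsing/writing),
`context` (count network and smoothing), `conflicts` (overlap rules and
clique covers), `scoring` (objective, first-order-Markov comparison score,
curated-threshold baseline), `solve` (elimination, ILP, oracle), `bench`
(FDR estimation, decoy labeling, synthetic instance generator), `cli`.

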