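# semnetkit

Toolkit for building semantic networks from distributional semantic
models (DSMs) and free-association norms, characterizing their
small-world / scale-free / hierarchical structure, and simulating their
emergence with a growing-network model that mixes preferential
("semantic differentiation") and random ("experiential correlation")
attachment.

## What's inside

| module | role |
| --- | --- |
| `semnetkit.corpusio` | corpus / association-norms readers, synthetic corpus generator with paradigmatic clusters and syntagmatic collocation pairs |
| `semnetkit.dsm` | word-document and window-2 word-word count matrices, tf-idf (log-entropy) and ppmi weighting, truncated-SVD smoothing, cosine similarity |
| `semnetkit.netbuild` | directed networks from norms, the k-nn method (external out-degree sequence), the cumulative-similarity (cs) method with optional minimum-cosine cutoff, and R tuning |
| `semnetkit.netstats` | components, ⟨k⟩, k_max, diameter, average shortest path, clustering, uniform-G(n,m) baselines, C(k) ~ k^-beta hierarchy fit |
| `semnetkit.degreefit` | discrete power-law / truncated power-law / exponential MLE, KS-based k_min scan, semi-parametric bootstrap goodness of fit, 10-fold CV model selection, below-k_min fitting, exact samplers |
| `semnetkit.growth` | modified preferential+random growth simulator with per-edge labels and gamma-tuned component size, plus Barabasi-Albert and mixed per-edge baselines |
| `semnetkit.relclass` | paradigmatic/syntagmatic edge classification against a generic is-a taxonomy, syntagmatic fraction q, q-vs-hierarchy correlation |

## CLI

Every stage is exposed through the `semnetkit` command:

```sh
semnetkit gen-corpus --documents 500 --doc-length 50 --seed 1 -o corpus.txt
semnetkit build-matrix corpus.txt --context word --window 2 -o mat
semnetkit weight mat --scheme ppmi --context word -o wmat
semnetkit smooth wmat --dim 300 --context word -o vectors.tsv
semnetkit build-net wmat --method cs --r 0.9 --min-cosine 0.05 -o net.tsv
semnetkit build-assoc-net norms.csv --min-count 2 -o assoc.tsv
semnetkit stats net.tsv --directed --reps 10 --seed 7
semnetkit hierarchy net.tsv
semnetkit fitdegree net.tsv --kmin-max 50 --gof-sets 1000 --cv-folds 10 --seed 7
semnetkit grow --n 5018 --m 13 --model ST --gamma 0.95 --seed 7 -o grown.tsv
semnetkit tune-gamma --n 5018 --m 13 --target-ncc 4845 --step 0.005 --reps 50 -o tuned.tsv
semnetkit classify --net net.tsv --taxonomy isa.tsv --wordmap map.tsv --coord-depth 2
```

Matrices are stored as Matrix Market (`.mtx`) with sidecar `.rows`/`.cols`
label files; networks as TSV edge lists (`source<TAB>target[<TAB>label]`),
with GraphML export available from the API.

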