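# gdprio

Latent-factor prioritization of gene–disease associations over
heterogeneous similarity networks.

Genes and diseases are embedded in one D-dimensional latent space; a
pair's half squared distance is converted into a link probability
`P(link) = exp(-(||U_i - V_j||^2 / 2 + vartheta))` and the Bernoulli
likelihood of known links plus sampled negatives is maximized by
stochastic gradient ascent. Two graph-regularized variants exploit
gene–gene and disease–disease similarity: a **centroid** penalty pulling
each latent vector toward the similarity-weighted centroid of its
neighbors, and a **pairwise** penalty on similarity-weighted neighbor
distances, which also transfers signal to diseases with no known genes
(cold start).

The package covers the full workflow:

| module | role |
| --- | --- |
| `gdprio.network_io` | TSV edge-list readers/writers for the four network layers, identifier↔index maps, ranked-prediction tables |
| `gdprio.similarity` | cosine / mapped-Pearson similarity of ortholog–disease profiles, combination with a functional gene network, top-k neighbor sets |
| `gdprio.negative_sampling` | random-walk propensity scoring of unlabeled pairs and stratified negative draws |
| `gdprio.factor_model` | the probability map, likelihood, graph regularizers, gradients, SGD training, ranking, checkpoints |
| `gdprio.katz` | truncated (length ≤ 3) Katz walk-count baseline |
| `gdprio.evaluation` | threefold cross-validation, disease strata (single vs many known genes), top-k retrieval curves, (alpha, beta) grids |
| `gdprio.synthetic` | seeded synthetic benchmark with planted latent structure and a recovery report |
| `gdprio.cli` | `gdprio` command with simulate / similarity / sample / train / predict / evaluate / grid |

## CLI

Everything runs offline from seeded synthetic data:

```sh
gdprio simulate --out data/ --seed 7            # four TSV layers + truth table
gdprio similarity --ortholog data/ortholog_profiles.tsv \
    --gene-network data/gene_network.tsv --out data/gene_sim.tsv --metric vss
gdprio sample --assoc data/gene_disease.tsv --gene-sim data/gene_network.tsv \
    --disease-sim data/disease_similarity.tsv --out data/labeled.tsv
gdprio train --assoc data/gene_disease.tsv --gene-sim data/gene_network.tsv \
    --disease-sim data/disease_similarity.tsv --checkpoint model.json \
    --model pairwise --d 5 --alpha 0.5 --beta 0.5 --seed 7
gdprio predict --checkpoint model.json --out ranked.tsv --topk 100
gdprio evaluate --assoc data/gene_disease.tsv --gene-sim data/gene_network.tsv \
    --disease-sim data/disease_similarity.tsv --out curves.tsv --model pairwise
gdprio grid --assoc data/gene_disease.tsv --gene-sim data/gene_network.tsv \
    --disease-sim data/disease_similarity.tsv --out grid.tsv \
    --alphas 0.01,0.1,0.5 --betas 0.001,0.1,0.5
```

Model variants are `basic`, `centroid`, `pairwise` (aliases `model1`,
`model2` accepted). All tunables can also live in a flat YAML config
passed as `gdprio --config cfg.yaml <command>`; flags override the file,
unknown keys are rejected, and every run logs its seed and resolved
configuration.

Real data is supported as formats only: the association layer is a
two-column TSV (gene, disease), similarity layers are weighted edge lists
(a, b, weight), and ortholog profiles are (gene, nonhuman-disease[,
species]) with species-namespaced disease ids. Nothing is downloaded.

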