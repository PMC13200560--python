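# ichd-matrix

Matrix and graph embodiment of the ICHD-3 primary headache criteria, for
headache researchers and diagnostic-classification informaticians who want
to analyse — or compute with — the structure of the classification itself.

The International Classification of Headache Disorders (3rd edition)
defines each primary headache disorder by criteria over Boolean clinical
*characteristics* ("photophobia", "4 to 72 h", "no nausea/vomiting", …).
This package treats each disorder as a negation-free Boolean formula built
from AND, OR and *at-least-k-of-n* connectives, and expands it into
disjunctive normal form: each conjunctive clause is a *phenotype* — one
complete way a patient can satisfy the criteria.  Phenotypes become the
rows and characteristics the columns of a 0/1 biadjacency matrix **M**,
with M(X, Y) = 1 iff phenotype X contains characteristic Y.  On top of
this matrix the package provides:

- **Bipartite projection** — weighted one-mode graphs M·Mᵀ (phenotypes)
  and Mᵀ·M (characteristics); the weight of a pair is its number of
  shared neighbors on the opposite axis.
- **Markov clustering (MCL)** with modularity-guided selection of the
  expansion and inflation parameters (Newman–Girvan Q on the unipartite
  view of the bipartite graph).
- **Exact row reduction** (RREF over the rationals, no floating point):
  the pivot columns are the basis characteristics spanning the vector
  space in which all phenotypes live.
- **Automated diagnosis by the row-sum theorem**: a patient's 0/1
  response vector v satisfies phenotype row i exactly when (M·v)ᵢ equals
  the i-th row sum — equivalent to evaluating the disorder's Boolean
  formula directly.
- A bundled, reviewed encoding of the ICHD-3 primary headaches (first
  two classification levels; complications of migraine, the episodic
  syndromes and all secondary headaches excluded), plus a random
  criteria generator for property testing.

## Worked example

```python
from ichd_matrix import (bundled_matrix, project, top_weight_pairs,
                         basis_characteristics, ResponseVector, diagnose)

m = bundled_matrix()           # 764 phenotypes x 103 characteristics
g = project(m, "characteristics")
print(top_weight_pairs(g, 1))  # strongest characteristic pairing
print(len(basis_characteristics(m, include_probable=False)))

v = ResponseVector({"clearly remembered onset": 1, "constant": 1,
                    "unremitting within 24 h": 1, "more than 3 months": 1})
print(diagnose(m, v).diagnosed_disorders)
```

prints

```
(204, [('greater than 15 days per month', 'more than 3 months')])
63
('ndph',)
```

The strongest characteristic pairing is the chronicity pair — 204
phenotypes (every chronic migraine, chronic tension-type and related
probable phenotype) require both "greater than 15 days per month" and
"more than 3 months".  Exact row reduction after dropping the "probable"
diagnoses leaves 63 pivot columns: definitive primary headache diagnoses
live in a 63-dimensional vector space.  The response vector carrying
exactly the four new-daily-persistent-headache characteristics satisfies
row `ndph1` and nothing else.

The `examples/` directory holds one short narrative script per
capability (expansion, projection, clustering, basis, diagnosis); each
builds its input, runs the method and explains the numbers it prints.
A thin CLI mirrors the library:

```bash
ichd-matrix build --out matrix.csv
ichd-matrix project --matrix matrix.csv --axis characteristics --top 3
ichd-matrix cluster --matrix matrix.csv --inflation 3.3 --expansion 3 --out clusters.tsv
ichd-matrix rref --matrix matrix.csv --exclude-probable
ichd-matrix diagnose --matrix matrix.csv --responses responses.yaml
```

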