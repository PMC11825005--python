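# awge-espca

Sparse principal component analysis for gene expression matrices whose
probes span wildly different expression scales — the situation typical of
insect RNA-seq (FPKM) data, where a handful of probes with enormous values
dominates every variance-based method and drags principal components away
from the biologically structured signal.

The package implements three related estimators over a probes × samples
matrix $X \in \mathbb{R}^{m \times n}$, all solving the rank-1 problem

$$\max_{\|u\|_2 \le 1,\ \|v\|_2 \le 1} u^\top X v \quad \text{s.t. } u \text{ sparse}$$

by alternating power iterations $u \leftarrow \mathcal{P}(Xv)$,
$v \leftarrow X^\top u / \|X^\top u\|$, with Hotelling deflation
$X \leftarrow X - d\,u v^\top$ for further components:

- **SPCA** — the classical $L_0$ constraint $\|u\|_0 \le s$: the projection
  $\mathcal{P}$ keeps the $s$ largest-magnitude entries of $Xv$.
- **ESPCA** — edge-group sparsity over a gene interaction network
  $G = \{e_1, \dots, e_E\}$: each edge $e_h = (i,j)$ scores
  $w_h = u_i^2 + u_j^2$, the top-$k$ edges are kept, and every probe incident
  to a kept edge survives (selecting an interaction admits both partners).
- **AWGE-ESPCA** — the edge-group model extended with two mechanisms:
  1. an *adaptive noise-elimination regularizer*: Tukey-style quantile
     fences $[Q_1 - 1.5\,\mathrm{IQR},\ Q_3 + 1.5\,\mathrm{IQR}]$ are
     computed on the current loading vector and probes falling outside are
     eliminated — excessive-expression probes are removed *by the data
     themselves*, not by manual pre-filtering;
  2. a *weighted gene interaction network*: each probe's count of
     target-relevant pathways is min–max-normalised onto $[a, b]$ and the
     edge score becomes $w_h = w_{qi} u_i^2 + w_{qj} u_j^2$, steering
     selection toward annotated pathway regions.

  Edge selection is greedy with decaying exploration: the candidate pool is
  the top $\lceil (1+\omega) k \rceil$ edges, $k$ are sampled uniformly, and
  $\omega$ shrinks by $\rho$ per iteration until the selection is exact
  top-$k$.

A seeded simulation module reproduces the support-recovery study the method
is built around: two planted sparse factors in a 12 × 100 matrix, four
pure-noise probes with uniform expression in [200, 300], and a 16-edge
network containing decoy edges that join true-signal probes to noise probes.

## Worked example

```python
import numpy as np
from awge_espca import AWGESparsePCA, make_network, simulate_matrix
from awge_espca.simulate import SimulationSpec

data, truth = simulate_matrix(SimulationSpec(), rng=np.random.default_rng(0))
results = AWGESparsePCA(data, make_network(), seed=1).fit()
print(results.summary())
```

```
AWGESparsePCA fit: 12 probes x 100 samples, 2 component(s)
------------------------------------------------------------------------
 component   sing.value  |support|  n_iter  converged  excluded
       PC1     167.4437          4       6       True         4
       PC2      34.6228          3       7       True         5
------------------------------------------------------------------------
PC1 support: Var1=-0.583, Var2=-0.498, Var3=-0.380, Var4=-0.517
PC2 support: Var5=+0.413, Var7=-0.773, Var8=+0.482
```

PC1 lands exactly on the first planted factor (Var1–Var4) and PC2 inside
the second (Var5–Var8); the four noise probes Var9–Var12 — whose raw
expression dwarfs every signal probe — received zero loadings in both
components (the `excluded` column counts the probes the regularizer fenced
out). For comparison, the same data fitted with plain `SparsePCA(data, s=4)`
puts its entire support on Var9–Var12, and `EdgeSparsePCA` is pulled onto
the noise block through the decoy edges.

The same workflow is available from a shell:

```sh
awge-espca simulate --out-dir sim --seed 0
awge-espca fit --expr sim/expr.tsv --edges sim/edges.tsv --seed 1 --out run
awge-espca score --loadings run_loadings.tsv --truth sim/truth.json
awge-espca ablate --expr sim/expr.tsv --edges sim/edges.tsv --truth sim/truth.json
```

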