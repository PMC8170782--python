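# citegraph

Predicting single-cell surface-protein abundance from RNA expression with a
graph neural network that embeds protein–protein-interaction (PPI) prior
knowledge.

CITE-seq measures the transcriptome and a panel of N surface proteins
(antibody-derived tags, conventionally CLR-transformed and therefore
possibly negative) in the same cells.  Given a denoised cells × genes RNA
matrix, this package trains a multi-label regressor that predicts all N
protein abundances per cell at once, letting the proteins inform each other
through a learned interaction graph and through external association scores
(e.g. STRING evidence channels).

## Model

Per cell with expression vector x ∈ R^G:

1. **RNA encoder** — two fully-connected layers G → 1024 → 128 (PReLU
   between them) give the RNA representation.
2. **Protein heads** — N independent affine maps 128 → d_r give
   V_r ∈ R^{N×d_r}, one feature vector per protein.
3. **Knowledge embedding** — M symmetric N × N prior score matrices are
   encoded column-wise by N shared one-layer networks (N → d_c), merged
   across channels with softmax attention and per-channel d_c × d_c mixing,
   re-weighted per protein with a second softmax attention, and concatenated
   into V_k ∈ R^{N×d_k} with d_k = N·d_c.
4. **Graph propagation** — node matrix V = [V_r ⊕ V_k] ∈ R^{N×d}
   (d = d_r + d_k) undergoes one round V^e = σ(A V W) with trainable dense
   adjacency A ∈ R^{N×N} and relation matrix W ∈ R^{d×d}.
5. **Predictor** — a shared affine map d → 1 with PReLU (slope 0.25), so
   predicted log-scale abundances can be negative: Ŷ = PReLU(FF(V^e)).

The loss is the per-cell sum over proteins of squared error, averaged over
the batch; Adam optimizes all parameters jointly (the knowledge-embedding
weights included), and the parameters of the epoch with the lowest training
loss are kept (best-epoch checkpointing).  Evaluation reports per-protein
MSE and Pearson correlation (PCC) on a held-out 30% of cells, with a
best-of-k protocol across independently seeded runs.

A synthetic-data generator (`citegraph.simulate`) produces paired
RNA/protein matrices driven by latent gene programs coupled through a known
interaction graph, plus noisy prior-feature channels correlated with that
graph, so the full train/predict/evaluate cycle runs with no download.

## Worked example

```python
from citegraph import SimConfig, simulate, GraphProteinRegressor, evaluate

expr, prot, priors, truth = simulate(SimConfig(seed=0))   # 2000 cells, 300 genes, 10 proteins
est = GraphProteinRegressor(
    priors=priors, hidden=(256, 64), d_r=16, d_c=8,
    epochs=40, batch_size=64, learning_rate=1e-3, random_state=0,
)
est.fit(expr.values[:1400], prot.values[:1400])
res = evaluate(est.checkpoint_, expr.values[1400:], prot.values[1400:], prot.protein_ids)
print(f"best epoch {est.best_epoch_} / {est.epochs}, training loss {est.best_loss_:.4f}")
print(f"test mean PCC {res.pcc_mean:.3f} (SD {res.pcc_sd:.3f})")
print(f"test mean MSE {res.mse_mean:.3f} (SD {res.mse_sd:.3f})")
```

prints

```
best epoch 39 / 40, training loss 0.8234
test mean PCC 0.623 (SD 0.040)
test mean MSE 0.101 (SD 0.006)
```

i.e. on a simulated panel with observation noise SD 0.3 on both modalities,
the model explains most of the recoverable signal (the noise ceiling on this
task is well below PCC 1); per-protein values live in `res.mse` / `res.pcc`.
The estimator follows the scikit-learn API (`get_params`, `clone`,
pipelines); `citegraph.train` / `citegraph.evaluate` expose the same
functionality functionally.

The same cycle is available from the shell:

```sh
citegraph simulate --out-dir data --seed 0
citegraph train --rna data/rna.csv --protein data/protein.csv \
    --priors data/priors.tsv --out model.npz --seed 1
citegraph predict --checkpoint model.npz --rna data/rna.csv --out pred.tsv
citegraph evaluate --checkpoint model.npz --rna data/rna.csv \
    --protein data/protein.csv --out metrics.tsv
citegraph ablate --rna data/rna.csv --protein data/protein.csv \
    --priors data/priors.tsv --repeats 5 --out ablation.tsv
```

Every command writes a JSON manifest (config hash, seeds, input digests)
sufficient to re-run it bit-identically on the same platform.

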