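# afplatent

Antifreeze-protein (AFP) prediction from sequence via latent-space encoding
of the composition of k-spaced amino acid pairs (CKSAAP), with a jointly
trained sparse autoencoder + neural classifier, an imbalance-aware
evaluation suite, a planted-motif synthetic sequence generator, and
experiment drivers for latent-size / class-ratio ablations.

## The problem

AFPs let organisms survive sub-zero temperatures, but their sub-types share
almost no sequence or structural similarity, so homology search (BLAST,
PSI-BLAST) fails and supervised classifiers must work from weak, diffuse
sequence features. The available data are small and heavily imbalanced
(hundreds of AFPs against thousands of non-AFPs), which makes accuracy a
misleading metric and makes a 3600-dimensional descriptor an ill-posed
input for a classifier trained on a few hundred sequences.

## The method

**Features.** A sequence of length *L* is encoded by CKSAAP: for each gap
*j* = 0…*k*, count every ordered residue pair (s\[i\], s\[i+j+1\]) and divide
by the number of windows *N_j* = *L* − (*j* + 1). Block *j* lists the 400
pair frequencies in lexicographic order (AA, AC, …, YY); the full
descriptor concatenates blocks *j* = 0…*k*, giving 400·(*k*+1) entries —
3600 at the default *k* = 8. Each block sums to 1 and the vector to *k*+1.

**Model.** A bottleneck network trained for two tasks at once:

* encoder `input → 50 → 25 → 25 → 10 → LV` (latent space, default LV = 4),
* decoder mirroring the encoder back to the input,
* classifier `LV → 10 → 10 → 10 → softmax(2)` reading the same latent space.

All autoencoder layers are ReLU with 30 % dropout after each hidden layer;
the joint loss is

```
w_recon · MSE(X, X̂)  +  w_class · CE(y, ŷ)  +  λ · mean(|z|)
```

with an L1 activity penalty (λ = 1e-4) keeping the latent activations *z*
sparse. Optimization is RMSprop with a stratified 90:10 train/validation
split and early stopping (patience 50) on the combined validation loss,
restoring the best weights. The network is implemented directly on numpy
(hand-written backpropagation, verified against finite differences in the
test suite).

**Evaluation.** Sensitivity, specificity, accuracy, precision, MCC,
balanced accuracy = (sens + spec)/2, Youden's index = sens + spec − 1, and
F1, all from the TP/FP/TN/FN tallies with AFP the positive class. MCC,
balanced accuracy and Youden are emphasized because the natural test sets
are ~50:1 imbalanced.

**Synthetic benchmark.** Real AFP benchmark sets are not bundled. The
`synthetic` module generates two sequence classes that differ only by
planted enrichment of chosen k-spaced residue pairs (default: the ordered
pair A…C at gap 3, planted 10 times per positive sequence), so the whole
encode → train → evaluate chain is testable with a known ground truth.

## Worked example

```python
import afplatent as ap

spec = ap.SyntheticSpec(n_pos=250, n_neg=250, seed=42)
records, labels = ap.generate_dataset(spec)
X, ids = ap.encode_dataset(records, ap.CKSAAPConfig(k=8))
train_idx, test_idx = ap.ratio_split(labels, "1:1", 150, seed=42)

result = ap.run_experiment(
    X[train_idx], labels[train_idx], X[test_idx], labels[test_idx],
    ap.JointModelConfig(input_dim=X.shape[1], latent_dim=4),
    ap.TrainConfig(max_epochs=300, early_stop_patience=50, seed=42),
)
for name, value in result.report.formatted().items():
    print(f"{name:18s} {value}")
print(f"{'test MSE (dB)':18s} {result.test_mse_db:.2f}")
```

prints

```
sensitivity        98.0%
specificity        98.0%
accuracy           98.0%
precision          98.0%
balanced_accuracy  98.0%
youden             0.96
mcc                0.96
f1                 0.98
test MSE (dB)      -45.83
```

i.e. on 150 + 150 training sequences the LV = 4 model recovers the planted
class signal almost perfectly on the 100 + 100 held-out sequences, and the
decoder reconstructs the 3600-dimensional descriptors with a mean squared
error around 10⁻⁴·⁶ (−45.8 dB). On real AFP data — which is far noisier
than any planted signal — published balanced accuracies for this family of
methods sit near 90 %, so treat synthetic numbers as an upper bound.

The same workflow is available from a shell:

```bash
afplatent simulate --spec spec.yaml --out-prefix sim
afplatent encode   --fasta sim.fasta --k 8 --out sim.tsv
afplatent train    --features sim.tsv --labels sim.labels.tsv --lv 4 --out model.npz
afplatent predict  --model model.npz --features sim.tsv --out pred.tsv
afplatent eval     --truth sim.labels.tsv --pred pred.tsv
afplatent ablate   --features sim.tsv --labels sim.labels.tsv --lv 2,4 \
                   --ratios 1:1,1:3 --runs 3 --n-pos-train 100 --fast --out grid.tsv
```

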