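# promgraph

Promoter prediction from fixed-length DNA windows centered on a putative
transcription start site (TSS), for researchers in regulatory genomics
who want a transparent, fully reproducible baseline that combines
sequence-local nucleotide encodings with graph-derived global context.

## The model

Each window of length *L* (e.g. the [−249, +50] 300-bp convention) is
encoded by four per-nucleotide schemes:

* **NCP** — chemical-property triples (r, h, f): ring structure,
  hydrogen-bond strength, functional group; A=(1,1,1), C=(0,0,1),
  G=(1,0,0), T=(0,1,0);
* **ND** — nucleotide density, the prefix frequency
  ND(nᵢ) = (1/i)·Σ_{k≤i} [n_k = nᵢ], fused with NCP into (r, h, f, nd)
  quadruples;
* **EIIP** — electron–ion interaction pseudopotential energies
  (T 0.1335, A 0.1260, G 0.0806, C 0.1340);
* **BPB** — bi-profile Bayes: position-specific nucleotide frequencies
  p⁺ from positive and p⁻ from negative *training* windows.

The m sample vectors then become nodes of a similarity graph learned by
the fast linear neighborhood similarity approach (FLNSA): minimise

    ½‖X − (C∗W)X‖²_F + (μ/2)‖(C∗W)e − e‖²,   W ≥ 0,

where C marks each row's k nearest neighbors, via the multiplicative
update W ← W ⊙ (XXᵀ+μeeᵀ)/((C∗W)XXᵀ+μ(C∗W)eeᵀ). The graph is embedded at
three scales — biased random walks + skip-gram (node), modularity-matrix
eigenvectors (community), and k-step transition-matrix SVD (global) —
and the concatenated local + embedding features feed a gradient-boosted
decision-tree ensemble (LightGBM). Evaluation reports Sen, Spe, Acc,
MCC, Pre, F1, AUC and Cohen's kappa.

See `docs/methods.md` for assumptions, defaults, and limitations.

## Worked example

Generate a synthetic benchmark (TATA-box consensus `TATAAA` planted
25–35 bp upstream of the TSS in every positive; Markov exon/intron-like
negatives with a 0.10 GC gap) and run the full pipeline:

```python
import promgraph as pg

dataset, truth = pg.generate_dataset(
    pg.SyntheticConfig(n_pos=200, n_neg=200, seed=1))
result = pg.run_experiment(dataset, pg.ExperimentConfig(seed=1))
print({k: round(v, 4) for k, v in result.metrics.to_dict().items()
       if k != "counts"})
```

```
{'sen': 0.85, 'spe': 0.775, 'acc': 0.8125, 'mcc': 0.6268, 'pre': 0.7907,
 'f1': 0.8193, 'auc': 0.92, 'kappa': 0.625}
```

The 400 windows were split 4:1 with stratification; the bi-profile Bayes
profiles and the classifier saw only the 320 training rows, while the
similarity graph and its embeddings were built transductively over all
400. The held-out AUC of 0.92 means the model ranks a random promoter
above a random non-promoter 92% of the time; kappa 0.625 is the
chance-corrected agreement of the thresholded calls. A permuted-label
control run under the same seed lands at AUC 0.4888 — chance level — so
the signal is the planted motif and composition, not leakage.

The same run is available from the shell:

```bash
promgraph simulate --n-pos 200 --n-neg 200 --out data/
promgraph run --config config.yaml --out runs/demo
promgraph ablate --config config.yaml --out ablation.tsv
```

Each run directory contains `metrics.json`, per-record predictions, the
graph edge list with provenance, the embeddings, the fitted BPB tables
and a manifest with per-stage seeds, timings and artifact checksums.

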