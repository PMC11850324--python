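# kgrdr

Drug–disease association prediction that fuses two complementary feature
views and decodes associations with a heterogeneous graph convolutional
network:

1. **Similarity integration** — profile-kernel (GIP) similarities are added
   to a stack of drug/disease similarity matrices; an entropy/redundancy
   selection step keeps the informative views, a spectral diffusion filter
   denoises each one, and a KL-divergence joint decomposition with
   graph-Laplacian regularization produces a common feature matrix **X**.
2. **Knowledge-graph embedding** — a (head, relation, tail) triple store is
   aligned with the benchmark's drug–disease edges and embedded with the
   complex-valued trilinear (ComplEx) model, giving topological features
   **Y** = [Re ‖ Im].
3. **Attention fusion** — X and Y are fused by iterative multiscale channel
   attention (two gating stages; gates from pooled global + pointwise local
   bottleneck contexts) into **Z**.
4. **Prediction** — kNN graphs over fused-feature similarities plus the
   binary association matrix form a heterogeneous network; layered
   intra-/inter-domain GCN passes (bilinear + mean cross-domain
   aggregation), layer attention, and a sigmoid inner-product decoder are
   trained end-to-end (fusion parameters included) with class-weighted BCE.

Everything is pure numpy/scipy — the training loops run on a small built-in
reverse-mode autodiff engine (`kgrdr.autodiff`), so no deep-learning
framework is required.

## CLI

Generate a synthetic benchmark-shaped input set, then run the pipeline:

```bash
kgrdr simulate --out fixtures/ --seed 0
kgrdr run --inputs fixtures/ --out runs/full --seed 0            # with 10-fold CV
kgrdr run --inputs fixtures/ --out runs/ablate --variant no_kg --no-cv
kgrdr predict --scores runs/full/scores.tsv \
    --interactions fixtures/interactions.tsv --disease disease::d000 --top 10
```

Stage-level commands (`integrate`, `embed`, `fuse`, `train`, `cv`) expose the
pipeline pieces individually. All commands accept `--config <yaml>`,
`--profile {desk,paper}` and `--seed`; the `desk` profile uses small
dimensions/epoch counts, `paper` the full published settings (epoch 4096,
feature dims 500, topk 15, Adam lr 0.05, dropout 0.4/0.2, ComplEx lr 0.1,
L2 1e-7). Each run writes `scores.tsv`, `metrics.json`,
`resolved_config.yaml`, `loss_trace.csv` and an I/O `audit.json`.

Ablation variants: `full`, `no_kg` (similarity features only), `no_gri`
(KG features only), `no_kg_gri` (first raw similarity per side straight to
the predictor).

## File formats

All artifacts are plain text: similarity matrices and feature/score tables
as dense TSV with identifier headers, interactions as dense 0/1 TSV or a
2-column edge list (auto-detected), triples as 3-column TSV, metrics as
JSON.

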