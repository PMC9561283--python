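"""Small-scale synthetic benchmark: does geography help prediction?

Generates a synthetic multi-isoform transcriptome with methylation planted
by the logistic geography model (long exons, last exon, stop-codon
proximity, plus a mild sequence-context preference), then trains the
geography-only CNN, the sequence-only CNN and the fused model and compares
their held-out AUCs.  Scaled down from the package's default benchmark
(700 genes, 2000 positives) so it finishes in about a minute.
"""

from geotx.experiments import run_synthetic_benchmark

result = run_synthetic_benchmark(seed=1, n_genes=220, n_positives=600)

print(f"train/test sites: {result.n_train}/{result.n_test}")
print(f"geography-only CNN AUC : {result.auc_geo:.3f}")
print(f"sequence-only CNN AUC  : {result.auc_seq:.3f}")
print(f"fused (geo+seq)   AUC  : {result.auc_gepse:.3f}")
print(f"isoform-MIL       AUC  : {result.auc_i_gepse:.3f}")
print(f"planted-truth oracle   : {result.auc_oracle:.3f}")
print(f"\nfused - sequence gap with geography planted : {result.gap_geo:+.3f}")
print(f"fused - sequence gap, geography-free labels : {result.gap_nogeo:+.3f}")
print("\nGeography alone predicts methylation well above chance; fusing it "
      "with sequence beats the sequence-only branch only when the labels "
      "actually depend on geography - the gap vanishes on geography-free "
      "data, showing the model is reading real geographic signal.")
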