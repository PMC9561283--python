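"""Isoform-attention recovery: which isoform carries the modification?

A genome-coordinate site often maps to several isoforms, and short-read
profiling cannot tell which isoform is methylated.  The attention-MIL
model learns a weight per isoform; under single-carrier conditions (one
witness isoform with favorable geography, siblings unfavorable) the
largest weight should point at the carrier.  Scaled down from the default
experiment (700 genes) to run in under a minute.
"""

from geotx.experiments import run_attention_recovery

rec = run_attention_recovery(seed=1, n_genes=250)

print(f"bags: {rec['n_train']} train / {rec['n_test']} test")
print(f"bag-level AUC: {rec['auc']:.3f}")
print(f"positive test bags where the top attention weight falls on the "
      f"signal-carrying isoform: {rec['attention_top_fraction']:.1%} "
      f"(n={rec['n_positive_bags']})")
print("\nThe attention weights are interpretable: they perform "
      "isoform-specific site assignment as a by-product of bag-level "
      "training, without ever seeing isoform-level labels.")
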