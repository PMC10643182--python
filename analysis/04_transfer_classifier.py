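#!/usr/bin/env python
"""Train the subtype transfer classifier and apply it to a validation cohort.

Trains the one-hidden-layer MLP on the discovery cohort's signature
z-scores (internal validation: repeated stratified 10-fold CV), then
generates an independent replicate cohort of the same study design,
z-scores it within itself, and classifies it — the synthetic analogue of
transferring subtype calls to an external validation cohort.
"""

import json
from pathlib import Path

import pandas as pd

import metabosubtype as ms
from metabosubtype.io_norm import write_json

ROOT = Path(__file__).resolve().parent.parent
SEED = 20260104

z = ms.read_expression(ROOT / "scratch" / "zscores.tsv", mode="zscore")
subtype_labels = pd.read_csv(ROOT / "results" / "03_subtypes.tsv", sep="\t",
                             index_col=0).iloc[:, 0].astype(str)
sig = ms.GeneSignature.from_dict(
    json.loads((ROOT / "results" / "02_signature.json").read_text()))

z_sig = z.restrict_genes(sig.gene_ids)
model = ms.train_classifier(z_sig, subtype_labels, seed=SEED,
                            cv_folds=10, cv_repeats=10)
write_json(model.to_dict(), ROOT / "results" / "04_classifier_model.json")

# independent validation cohort: same study design, new sampling noise
val_cfg = ms.SyntheticConfig(seed=SEED + 1)
val_expr, val_clin, val_truth = ms.generate_cohort(val_cfg)
val_z = ms.zscore_genes(ms.log_transform(
    ms.median_of_ratios_normalize(val_expr)[0]))
val_labels, proportions = ms.classify_external(model, val_z)

truth_lab = val_truth.true_subtype.map({"aggressive": "M2", "indolent": "M1"})
accuracy = float((val_labels == truth_lab.loc[val_labels.index]).mean())
logrank = ms.logrank_test(val_clin, val_labels)

write_json({
    "cv_accuracy_mean_pct": round(100 * model.cv_accuracy_mean, 1),
    "cv_accuracy_sd_pct": round(100 * model.cv_accuracy_sd, 1),
    "validation_proportions": proportions.round(4).to_dict(),
    "validation_accuracy_vs_truth": round(accuracy, 4),
    "validation_logrank_p": logrank.p,
}, ROOT / "results" / "04_classifier_summary.json")

print(f"internal validation accuracy: {100 * model.cv_accuracy_mean:.1f}% "
      f"± {100 * model.cv_accuracy_sd:.1f}% "
      f"(10-fold CV x 10 repeats, {len(sig)} input genes)")
print(f"validation cohort subtype proportions: "
      f"{ {k: round(v, 3) for k, v in proportions.items()} }")
print(f"validation accuracy vs planted subtype: {accuracy:.1%}")
print(f"validation M1 vs M2 log-rank p = {logrank.p:.3g}")
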