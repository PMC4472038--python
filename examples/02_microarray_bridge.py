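"""Score a microarray test set against an NGS training atlas.

Microarray intensities live on a different scale than sequencing counts,
so each array sample is mapped onto the training CPM scale with a robust
affine fit in log space anchored on housekeeping genes, then scored like
any other test set.
"""

import keygenes as kg

truth = kg.SimulationTruth.default(seed=0)
counts, labels = kg.simulate_tissue_counts(truth, samples_per_tissue=5, seed=1)
train_ids, test_ids = kg.holdout_split(labels, per_class=1, seed=2)

# microarray version of the held-out samples: 70% probe coverage, gain 0.9,
# background offset, gaussian noise in log space
array = kg.simulate_microarray(
    counts.select_samples(test_ids), truth,
    probe_fraction=0.7, noise_sd=0.2, gain=0.9, offset=2.0, seed=3,
)

train_cpm = kg.cpm(kg.filter_detected(counts.select_samples(train_ids)))
hk = kg.select_housekeepers(truth.housekeeper_panel(), train_cpm, array)
print(f"usable housekeeping anchors: {len(hk.housekeepers_used)}")

scaled = kg.scale_to_training(array, train_cpm, hk, mode="affine")
for sample, params in hk.sample_params.items():
    print(f"  {sample}: gain={params['gain']:.3f} offset={params['offset']:.2f} "
          f"median|resid|={params['median_abs_residual']:.3f}")
# measurement noise on the intensity side attenuates the fitted gain below
# the ideal 1/0.9 (regression dilution over the narrow housekeeper range);
# classification is robust to this because the scores depend on contrasts
# between tissues, not on the absolute calibration

top500 = kg.top_variable_genes(train_cpm, n=500)
model = kg.fit_classifier(
    train_cpm, labels.subset(train_ids), top500,
    test_genes=array.gene_ids, nfolds=10, seed=7,
)
calls = kg.predict_identity_scores(model, scaled).calls()
correct = sum(calls.loc[s, "best_class"] == labels.class_of(s)
              for s in calls.index)
print(calls[["best_class", "best_score"]])
print(f"\ncorrect calls after bridging: {correct}/{len(calls)}")
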