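"""Descriptive views of a tissue barcode: expression-level bins, sample
clustering, and within-tissue correlation using classifier genes versus
the top-500 variable genes.
"""

import keygenes as kg

truth = kg.SimulationTruth.default(seed=0)
counts, labels = kg.simulate_tissue_counts(truth, samples_per_tissue=5, seed=1)
cpm = kg.cpm(kg.filter_detected(counts))

# barcode bins for one tissue's markers: mean CPM per (gene, tissue) falls
# into <50 / 50-100 / 100-1000 / >1000 CPM bands
tissue = truth.tissues[0]
bins = kg.barcode_bins(cpm, labels, truth.markers[tissue][:5])
print(f"barcode bins for 5 {tissue} markers:")
print(bins[bins["class"] == tissue][["gene", "mean_cpm", "bin"]].to_string(index=False))

# hierarchical clustering on 1 - Pearson correlation, complete linkage
some_samples = [s for s in cpm.sample_ids if s.endswith(("_s1", "_s2"))]
sub = kg.ExpressionMatrix(cpm.data[some_samples], "cpm")
dendro = kg.cluster_samples(sub, sorted(truth.marker_union()))
print("\ndendrogram over marker genes (samples of the same tissue pair up):")
print(dendro.to_newick())

# markers give tighter within-tissue correlation than a random gene set
import numpy as np
markers = sorted(truth.marker_union())
rng = np.random.default_rng(4)
background = list(rng.choice(
    [g for g in cpm.gene_ids if g not in set(markers)], size=len(markers),
    replace=False))
for name, genes in [("160 random background genes", background),
                    ("160 planted markers", markers)]:
    table = kg.mean_group_correlation(cpm, labels, genes)
    overall = table[table.group == "__overall__"].iloc[0]
    print(f"mean within-tissue Pearson r over {name}: "
          f"{overall.mean_r:.3f} +/- {overall.sd_r:.3f}")
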