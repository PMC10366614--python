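"""Embed one scan's tvFC windows with the three manifold learners and score
task separability with the silhouette index.

Also shows the neighborhood-size failure mode: a too-small k yields an
embedding dominated by temporal autocorrelation ("spaghetti") with poor task
silhouette.
"""

import tvmanifold as tm
from tvmanifold.evaluation import scan_embed, silhouette_index

config = tm.SyntheticConfig(n_subjects=1, n_rois=30, seed=7)
timeseries, schedule, _ = tm.generate_dataset(config)[0]
tvfc = tm.compute_tvfc(timeseries, tm.WindowSpec(30, 1), schedule)

print(f"ambient-space SI_task = {silhouette_index(tvfc, 'task').value:.3f} "
      "(positive but small, as for raw connectivity)")

for k in (25, 75):
    emb = scan_embed(tvfc, "LE", {"k": k, "m": 3}, metric="correlation")
    si = silhouette_index(emb, "task").value
    print(f"LE  correlation k={k:<3} -> SI_task = {si:.3f}")

emb = scan_embed(tvfc, "TSNE",
                 {"perplexity": 75, "m": 2, "learning_rate": 10, "seed": 0},
                 metric="correlation")
print(f"T-SNE perplexity=75     -> SI_task = {silhouette_index(emb, 'task').value:.3f} "
      f"(final KL cost {emb.diagnostics['final_cost']:.3f})")

emb = scan_embed(tvfc, "UMAP",
                 {"k": 70, "m": 3, "learning_rate": 0.01, "seed": 0},
                 metric="euclidean")
print(f"UMAP k=70 lr=0.01       -> SI_task = {silhouette_index(emb, 'task').value:.3f}")
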