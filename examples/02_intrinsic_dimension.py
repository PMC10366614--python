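"""Estimate the intrinsic dimension of tvFC window clouds.

First validates the TwoNN and local-PCA estimators on samples with known
dimension, then estimates the dimension of a synthetic scan's window cloud —
which is orders of magnitude below the ambient connection count.
"""

import tvmanifold as tm

for d, kind in ((1, "linear-subspace"), (5, "uniform-cube")):
    x = tm.generate_manifold_sample(d, ambient_dim=50, n_points=2000, kind=kind, seed=2)
    print(f"{kind} with true d={d}: TwoNN estimates {tm.twonn_id(x):.2f}, "
          f"lPCA estimates {tm.lpca_id(x, 'global').value:.0f}")

config = tm.SyntheticConfig(n_subjects=1, n_rois=30, seed=7)
timeseries, schedule, _ = tm.generate_dataset(config)[0]
tvfc = tm.compute_tvfc(timeseries, tm.WindowSpec(30, 1), schedule)

est = tm.estimate_id(tvfc, estimator="twonn", scope="global")
print(f"\nglobal TwoNN ID of the window cloud: {est.value:.2f} "
      f"(ambient space has {tvfc.n_cons} dimensions)")

glob = tm.estimate_id(tvfc, estimator="lpca", scope="global")
local = tm.estimate_id(tvfc, estimator="lpca", scope="local", k=100)
print(f"lPCA ID: global {glob.value:.0f}, local (k=100) mean {local.mean:.2f} — "
      "local estimates sit at or below the global one")
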