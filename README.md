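# psishent

Patch size and shape entropy analysis of spatio-temporal categorical data.

`psishent` quantifies how the information carried by a categorical
variable *C* — land-cover classes, species groups, disease states — is
structured across space and time.  Instead of conditioning entropy on a
fixed regional support, it derives the spatio-temporal support from *C*
itself: spatial patches (connected cells where a category's occupation
fraction exceeds a threshold), temporal patches (maximal runs of
above-threshold time steps), their size classes **Si** and **Ti**, shape
classes **Sh**, and ordinal permutation motifs **Th**.  Crossing these
descriptors with *C* yields a multiway distribution table analysed two
complementary ways:

1. **Shannon entropy decomposition.**  With the normalised entropy
   Hu(X) = H(X)/log|X| the decomposition theorem takes the weighted form

       Hu(S, C) = w_S · Hu(S) + w_C · Hu(C|S),
       w_S = log|S| / (log|S| + log|C|),

   together with multiway mutual information
   MI = D_KL(p_STC ‖ p_S ⊗ p_T ⊗ p_C), conditional-entropy ratios
   p_s·H(C|S=s)/H(C|S), and per-cell map statistics restricted to
   locally occurring patch classes.

2. **Weighted multiway correspondence analysis.**  The ratio-to-
   independence tensor is expanded into rank-one terms,

       p_STC / (p_S ⊗ p_T ⊗ p_C) = 1 + Σ_r σ_r (v_Sr ⊗ v_Tr ⊗ v_Cr),

   with margin-weighted unit vectors (Σ_s p_s v_Srs² = 1) and
   Σ_r σ_r² = 1 + χ²/N for a complete two-mode decomposition.  Each
   component is summarised by its non-negative CTR-tensor
   (p_S v²) ⊗ (p_T v²) ⊗ (p_C v²) — a product distribution whose
   normalised entropy decomposes additively across modes — and by the
   analytic positive split of the signed term into at most 4 + 4
   orthogonal non-negative rank-one tensors.

The table values need not be plain occurrence counts: per-patch counts
(cancelling the cell-count baseline of large patches),
k-co-occurrences under a per-dimension collocation distance rule, and
distance-ratio weights are all supported.

A seeded synthetic generator (softmax of smoothed Gaussian random
fields with logit-scale trends) produces compositional grid time
series with tunable patchiness, so the whole pipeline is testable
without any external dataset.

## Worked example

```python
import numpy as np
import psishent as ps
from psishent.tables import patch_size_table

spec = ps.SimulationSpec(n_rows=12, n_cols=12, n_times=40, n_categories=6,
                         correlation_length=2.5, noise_scale=0.3,
                         trend_slopes=ps.default_trend_slopes(6, 0.02, seed=0),
                         seed=0)
grid = ps.simulate_composition(spec)

si = ps.SizeClassing(ps.SPATIAL_SIZE_CLASSES)    # 1, 2, >2, >7, >25, >50, >100
ti = ps.SizeClassing(ps.TEMPORAL_SIZE_CLASSES)   # 1, 2, >2, >4, >7, >20, >30, >60
table, detail = patch_size_table(grid, si, ti, threshold=0.15)
print("table shape:", table.values.shape, " N =", int(table.total))

nonempty, _ = table.drop_empty()
rep = ps.decompose(nonempty, ["Si", "Ti", "C"])
print(f"Hu(Si)      = {rep.mode_Hu['Si']:.7f}")
print(f"Hu(Ti|Si)   = {rep.conditional_Hu['Ti|Si']:.7f}")
print(f"Hu(C|Si,Ti) = {rep.conditional_Hu['C|Si,Ti']:.7f}")
print(f"Hu(joint)   = {rep.joint_Hu:.7f}")
print(f"MI          = {rep.mutual_information:.7f}")

res = ps.decompose_fca(table, n_components=3, seed=0)
print("sigma:", np.round(res.sigmas, 4))
print("shares %:", np.round(res.shares(), 2))
ce = ps.ctr_entropy(res.components[0])
print("independence CTR Hu:", {k: round(v, 3) for k, v in ce["per_mode"].items()},
      "combined:", round(ce["combined"], 3))
```

Output:

```
table shape: (7, 8, 6)  N = 10133
Hu(Si)      = 0.7094373
Hu(Ti|Si)   = 0.3477768
Hu(C|Si,Ti) = 0.3485289
Hu(joint)   = 0.4718371
MI          = 1.0372966
sigma: [1.     0.6852 0.5824 0.2839]
shares %: [22.47 10.55  7.62  1.81]
independence CTR Hu: {'Si': 0.709, 'Ti': 0.398, 'C': 0.873} combined: 0.654
```

Reading it: the 7×8×6 table crosses spatial size class, temporal size
class and category over 10,133 cell-level patch memberships.  Spatial
patch sizes are fairly even (Hu(Si) = 0.71) while, given a spatial
class, temporal classes and categories are strongly concentrated
(conditional Hu ≈ 0.35) — the three descriptors are far from
independent (MI = 1.04 nats).  The correspondence analysis agrees: the
pure independence component carries only 22.5 % of the variability, and
the first extracted interaction another 10.6 %.  Within the
independence part, temporal patch structure is the most structuring
dimension (lowest CTR entropy, Hu = 0.398).

The same workflow runs from the shell:

```sh
psishent run --seed 7 --out results/demo        # simulate -> patches -> table -> entropy + FCA
psishent simulate --seed 3 --out grid.csv       # the individual stages
psishent tabulate --input grid.csv --out table.csv
psishent entropy --table table.csv --out report.csv
psishent fca --table table.csv --out fca_out
```

`run` writes a `manifest.json` with SHA-256 checksums of every
artifact; identical seeds give identical checksums.

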