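"""IC50 normalization and the binder threshold.

Binding assays report IC50 in nM (lower = stronger binding). Models train
on the normalized scale 1 - log(IC50)/log(50000), which maps 1 nM -> 1.0
and 50 000 nM -> 0.0. The conventional binder cutoff of 500 nM lands at
0.426 on this scale.
"""

from mhc2bind import binarize, inverse_transform, transform_ic50

for ic50 in (1.0, 50.0, 500.0, 5000.0, 50000.0):
    aff = transform_ic50(ic50)
    print(f"IC50 {ic50:>8.0f} nM -> affinity {aff:.3f} "
          f"({'binder' if binarize(aff) else 'non-binder'})")

# the transform inverts exactly away from the clamp
print(f"\naffinity 0.426 -> IC50 {inverse_transform(0.426):.1f} nM "
      "(just under the 500 nM binder cutoff)")
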