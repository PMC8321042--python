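"""Compute the per-slide positivity indices and histogram features.

Takes one hand-written tile-probability vector and prints P1* (mean tile
probability), the binary indices P1/P2/P3, and the decile-bin frequencies
F0.5..F0.9 — the slide's row of the tabular feature matrix.
"""

from her2mil import compute_features

p = [0.95, 0.88, 0.71, 0.64, 0.52, 0.45, 0.30, 0.12, 0.08, 0.55]
features = compute_features("example_slide", p)

print(f"T = {features.T} tiles")
print(f"P1* = {features.P1_star:.3f}  ->  P1 = {features.P1}")
print(f"P2 = {features.P2}   (mean of p*1[p>=0.5] over all tiles, cutoff 0.66)")
print(f"P3 = {features.P3}   (fraction of tiles with p>=0.5, cutoff 0.35)")
for h, v in features.F.items():
    print(f"F{h} = {v:.2f}")

# 6 of 10 tiles clear 0.5, so P3 = 1 (0.6 >= 0.35); the masked mean
# (0.95+0.88+0.71+0.64+0.52+0.55)/10 = 0.425 stays below 0.66, so P2 = 0;
# the plain mean 0.52 >= 0.5 makes P1 = 1. The F bins sum to the 0.6
# super-threshold fraction.
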