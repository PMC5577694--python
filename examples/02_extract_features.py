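"""Extract the 363 texture features from one masked image.

Feature families: moment-based (76), histogram (16), Markovian /
co-occurrence (93), regional (48), run-length (60), Fourier (33),
wavelet (37).
"""

from collections import Counter

import mammotex as mx

image = mx.generate_mammogram(256, 256, target_pmd=40.0, texture_scale=8,
                              seed=5)
features = mx.extract_features(image)

counts = Counter(mx.family_of(name) for name in features.index)
print(f"{len(features)} features:",
      ", ".join(f"{fam} {n}" for fam, n in counts.items()))
print()
for name in ("moment.mean", "histogram.bin08", "markovian.contrast.a000",
             "runlength.sre.a000", "regional.log_count.t128",
             "fourier.centroid_radius", "wavelet.efrac.hh.L1"):
    print(f"  {name:28s} {features[name]:12.5f}")

# Higher target density brightens the image: the mean gray value and the
# upper histogram bins rise, while run-length and co-occurrence statistics
# react to the spatial granularity set by texture_scale.
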