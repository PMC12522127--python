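"""Predicted precipitate morphology for the salts in the 2D-Hofmeister scheme."""

import fibrion as fb
from fibrion.hofmeister import supported_ions

cations, anions = supported_ions()
print(f"{'':10s}" + "".join(f"{a:>10s}" for a in anions))
for cat in cations:
    row = [fb.classify_pair(cat, an).predicted_morphology[:9] for an in anions]
    print(f"{cat:10s}" + "".join(f"{m:>10s}" for m in row))
# dense_fib = dense fiber networks (kosmotropic pairs, e.g. Na-phosphate);
# smooth = featureless film (chaotropic pairs, e.g. MgCl2); the mixed
# quadrants give coarse/localized fibers or rough non-fibrous deposits.
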