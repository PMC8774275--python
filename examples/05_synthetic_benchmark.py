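"""Recovery power of the full pipeline across effect sizes.

Sweeps the planted fold-change effect and reports mean recovery
Jaccard, showing how detectability grows with signal strength.
"""

import numpy as np

from sdanet import SyntheticSpec, planted_recovery

for effect in (0.5, 1.0, 1.5, 2.0):
    js = [planted_recovery(SyntheticSpec(lfc_effect=effect), seed)[0]
          for seed in range(8)]
    bar = "#" * int(20 * np.mean(js))
    print(f"lfc_effect={effect:3.1f}  mean Jaccard={np.mean(js):.3f}  {bar}")
# Below the |logFC|>=1 filter threshold nothing is recoverable; once the
# planted shift clears it, recovery rises towards near-perfect overlap.
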