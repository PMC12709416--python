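"""Region extraction and composition statistics on a disordered scaffold.

Builds a synthetic 1000-residue sequence, slices the two working regions of
the MUT-16 scaffold by parent numbering (M8BR 633-772, FFR 773-944), and
prints their aromatic content — the composition feature that separates the
phase-separating region from the client-binding one.
"""

import numpy as np

from slabsim import (
    MUT16_REGIONS,
    SequenceRecord,
    composition_fraction,
    extract_region,
)
from slabsim.params import CANONICAL_CODES

rng = np.random.default_rng(0)
residues = "".join(rng.choice(list(CANONICAL_CODES), size=1000))
seq = SequenceRecord("synthetic-scaffold", residues)

for name in ("M8BR", "FFR", "M8BR_FFR"):
    region = MUT16_REGIONS[name]
    sub = extract_region(seq, region)
    pct = composition_fraction(sub, "FYW")
    print(f"{name:9s} residues {region.start}-{region.end} "
          f"({len(sub):3d} aa): {pct:5.1f}% aromatic (F/Y/W)")

# A uniform random sequence carries ~15% aromatics (3 of 20 letters); in the
# real scaffold the foci-forming region holds ~3x the aromatic fraction of
# the client-binding region, which is why it drives phase separation.
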