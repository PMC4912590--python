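#!/usr/bin/env python
"""Hydrogen-bond counting for the three dimethylurea conformer states.

Builds coordinate frames whose contact schedules match the published
solvation-shell rates per conformer state (carbonyl acceptor / amide
donors: trans/trans 1.69 + 0.88, cis/trans 1.60 + 0.57, cis/cis
1.51 + 0.72) and verifies the geometric counter (3.0 A heavy-atom
distance, 135 degree angle) returns exactly those means.
"""

import json
from pathlib import Path

from ureaconf import synth
from ureaconf.hbond import hbond_count
from ureaconf.synth import HBondGroupSpec

OUT = Path(__file__).resolve().parent.parent / "results" / "05_hbond"
OUT.mkdir(parents=True, exist_ok=True)

STATES = {
    "trans_trans": (1.69, 0.88),
    "cis_trans": (1.60, 0.57),
    "cis_cis": (1.51, 0.72),
}

summary = {}
for state, (carbonyl, amide) in STATES.items():
    frames = synth.gen_hbond_frames(
        [
            HBondGroupSpec("carbonyl_acceptor", "acceptor", carbonyl),
            HBondGroupSpec("amide_donor", "donor", amide),
        ],
        n_frames=100,
        seed=0,
    )
    means, total = hbond_count(frames)
    summary[state] = {**means, "total": total}
    print(f"{state}: carbonyl {means['carbonyl_acceptor']:.2f}, "
          f"amides {means['amide_donor']:.2f}, total {total:.2f}")

(OUT / "summary.json").write_text(json.dumps(summary, indent=1))
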