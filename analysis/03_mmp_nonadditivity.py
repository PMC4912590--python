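#!/usr/bin/env python
"""Matched-pair and transformation-cycle non-additivity analysis.

Three generated SAR tables exercise the chain end to end:
 1. a purely additive table — every double transformation cycle closes to
    zero non-additivity;
 2. the worked-example cycle — a substitution worth 2.5 log units in one
    linker context but only 0.85 in the other, a non-additivity of
    1.65 log units;
 3. additive substituent effects spanning six log units — the maximum
    matched-pair difference equals the span.
"""

import json
from pathlib import Path

from ureaconf import pipeline, synth
from ureaconf.synth import SarGeneratorSpec

OUT = Path(__file__).resolve().parent.parent / "results" / "03_mmp"
OUT.mkdir(parents=True, exist_ok=True)

summary = {}

additive = pipeline.cmd_mmp(
    synth.gen_sar_table(SarGeneratorSpec(effects1=(0.0, 0.75), effects2=(0.0, 1.25)))
)
summary["additive_max_abs_nonadditivity"] = additive["summary"]["max_abs_nonadditivity"]
print("additive table:", additive["summary"]["n_pairs"], "pairs,",
      additive["summary"]["n_cycles"], "cycles, max |non-additivity| =",
      additive["summary"]["max_abs_nonadditivity"])

cycle_spec = SarGeneratorSpec(
    effects1=(0.0, 0.5), effects2=(0.0, 2.5), gamma=((1, 1, -1.65),)
)
res = pipeline.cmd_mmp(synth.gen_sar_table(cycle_spec))
res["pairs_table"].to_csv(OUT / "pairs.csv", index=False)
res["cycles_table"].to_csv(OUT / "cycles.csv", index=False)
summary["worked_example_nonadditivity"] = res["summary"]["max_abs_nonadditivity"]
summary["worked_example_boost"] = max(p.delta for p in res["pairs"])
print("worked example: boost", summary["worked_example_boost"],
      "log units in one context; non-additivity",
      round(summary["worked_example_nonadditivity"], 2), "log units")

span = pipeline.cmd_mmp(
    synth.gen_sar_table(SarGeneratorSpec(effects1=(0.0, 6.0), effects2=(0.0, 0.5)))
)
summary["six_log_unit_max_delta"] = span["summary"]["max_abs_delta"]
print("6-log-unit additive span: max matched-pair |delta| =",
      span["summary"]["max_abs_delta"])

(OUT / "summary.json").write_text(json.dumps(summary, indent=1))
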