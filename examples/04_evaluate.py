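"""Score a generated set against a training set.

Computes the conditional metrics (validity/uniqueness/novelty), the
distribution metrics (SNN, fragment & scaffold similarity, internal
diversity), ring-system/functional-group coverage and recovery, and an
enrichment factor for a toy ranked screen.
"""

import json

from nimo.evaluation import enrichment_factor, evaluate

train = ["CC1CCCCC1", "CCc1ccccc1", "OC1CCCCC1", "c1ccc2ccccc2c1", "CCN1CCCC1"]
generated = ["CC1CCCCC1", "CCCc1ccccc1", "OC1CCCC1", None, "c1ccc2ccccc2c1C"]

report = evaluate(generated, train)
print(json.dumps(report, indent=2))
# validity counts reconstruction failures (None); novelty is the share
# of valid unique molecules absent from the training set; SNN near 1
# means the sample hugs the training distribution.

scores = [(1.0 - i / 10, i in (0, 1, 5)) for i in range(10)]  # 3 actives
ef = enrichment_factor(scores, fractions=[0.1, 0.2, 0.5, 1.0])
print("enrichment factors:", {f"{k:.0%}": round(v, 2) for k, v in ef.items()})
# EF[X] > 1 means the top X of the ranking holds more actives than a
# random pick; EF[100%] is 1 by definition.
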