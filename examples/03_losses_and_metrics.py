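"""The combined training objective and the assessment criteria.

The loss is L_total = L_wce + L_dice: a weighted cross-entropy plus a
soft dice over all three classes (epsilon = 1 keeps absent classes
well-defined).  The metrics block reproduces the standard one-vs-rest
criteria; note the exact Dice = 2*IoU/(1+IoU) relationship.
"""

import numpy as np

from thyroseg.losses import total_loss
from thyroseg.metrics import ConfusionCounts, compute_metrics

# a 2x2 toy image: 3 background pixels + 1 nodule pixel, with a model that
# confidently predicts all-background
logits = np.zeros((1, 3, 2, 2), dtype=np.float32)
logits[0, 0] = 8.0  # strong background logit everywhere
target = np.array([[[0, 0], [0, 2]]])
loss = total_loss(logits, target)
print(f"wce={float(loss.wce.data):.4f}  dice={float(loss.dice.data):.4f}  "
      f"total={float(loss.total.data):.4f}  (the missed nodule dominates)")

counts = ConfusionCounts(tp=8, fp=2, tn=88, fn=2)
m = compute_metrics(counts)
print("counts tp=8 fp=2 fn=2 tn=88 ->",
      "  ".join(f"{k}={v:.4f}" for k, v in m.items()))
print(f"identity check: 2*IoU/(1+IoU) = {2 * m['IoU'] / (1 + m['IoU']):.4f} = Dice")
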