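"""From motion maps to detection metrics.

Thresholds a motion intensity map into scored boxes (connected components),
matches them against ground truth at IoU > 0.25, and reports precision,
recall and average precision — the same plumbing the CLI `eval` command uses.
"""

import numpy as np

from magnosnn import DetectionBox, match_and_ap, motionmap_to_boxes
from magnosnn.evaluation import evaluate_detections

# a map with one strong blob (the target) and one faint speckle
motion_map = np.zeros((20, 30))
motion_map[8:12, 10:15] = 0.9
motion_map[2, 25] = 0.6

boxes = motionmap_to_boxes(motion_map, threshold=0.5)
print("detections:", [(b.xywh, round(b.score, 2)) for b in boxes])

gt_boxes = [np.array([[10, 8, 5, 4]])]  # one frame, one ground-truth box
report = evaluate_detections([boxes], gt_boxes, iou_threshold=0.25)
print(f"precision={report.precision:.2f} recall={report.recall:.2f} "
      f"AP={report.ap:.2f}")
print("the blob matches the ground truth; the speckle counts as a false "
      "positive, halving precision but not recall")
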