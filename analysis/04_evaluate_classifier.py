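#!/usr/bin/env python
"""Stage 4: repeated shuffle-split evaluation of the dual-network classifier.

100 stratified 80/20 splits by default, with structure re-learned inside
every iteration, plus the scale-2/7/8 logistic comparison model under the
identical protocol.  Writes eval_report.json.
"""

import argparse
import json
from pathlib import Path

from mmpibn.classifier import baseline_scale278, evaluate_rsscv
from mmpibn.io import read_cohort_csv

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out-dir", default="results")
parser.add_argument("--iterations", type=int, default=100)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

out = Path(args.out_dir)
matched = read_cohort_csv(out / "matched_cohort.csv")
report = evaluate_rsscv(matched, iterations=args.iterations, seed=args.seed)
baseline = baseline_scale278(matched, iterations=args.iterations,
                             seed=args.seed)
(out / "eval_report.json").write_text(json.dumps(
    {"dual_network": report.as_dict(),
     "scale278_logistic": baseline.as_dict()}, indent=1))
print(f"dual network: accuracy {report.accuracy_mean:.3f} "
      f"F1 {report.f1_mean:.3f} AUC {report.auc_mean:.3f}")
print(f"scale-278 logistic: accuracy {baseline.accuracy_mean:.3f} "
      f"AUC {baseline.auc_mean:.3f}")
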