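#!/usr/bin/env python
"""Stage 5: compare the two groups' correlation matrices.

Pearson matrices per stratum, their difference, and the label-permutation
test of global equality (Frobenius statistic).  Writes the matrices as CSVs
and the test summary as JSON.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from mmpibn.correlations import permutation_equality_test
from mmpibn.io import read_cohort_csv
from mmpibn.scales import CANONICAL_SCALES

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out-dir", default="results")
parser.add_argument("--n-perm", type=int, default=10000)
parser.add_argument("--seed", type=int, default=1)
args = parser.parse_args()

out = Path(args.out_dir)
matched = read_cohort_csv(out / "matched_cohort.csv")
comparison = permutation_equality_test(
    matched.stratum(0).profiles, matched.stratum(1).profiles,
    n_perm=args.n_perm, seed=args.seed)
names = list(CANONICAL_SCALES)
for tag, mat in (("healthy", comparison.corr_a),
                 ("schizophrenia", comparison.corr_b),
                 ("difference", comparison.difference)):
    pd.DataFrame(mat, index=names, columns=names).to_csv(
        out / f"correlations_{tag}.csv")
(out / "correlation_test.json").write_text(json.dumps({
    "statistic": comparison.statistic,
    "statistic_name": comparison.statistic_name,
    "p_value": comparison.p_value,
    "n_perm": comparison.n_perm}, indent=1))
print(f"Frobenius statistic {comparison.statistic:.4f}, "
      f"p = {comparison.p_value:.4g} ({comparison.n_perm} permutations)")
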