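#!/usr/bin/env python
"""Stage 3: learn one network per diagnostic group and save the classifier.

Hybrid structure learning (Fisher-z skeleton + BIC hill-climb) and maximum-
likelihood CPD fitting on each stratum of the matched cohort; writes the
fitted networks (JSON + GraphML with arc strengths), and the combined
classifier model.
"""

import argparse
from pathlib import Path

from mmpibn.classifier import fit_classifier
from mmpibn.gbn import arc_strength, dag_to_graphml, save_network
from mmpibn.io import read_cohort_csv, save_model

parser = argparse.ArgumentParser(description=__doc__)
parser.add_argument("--out-dir", default="results")
parser.add_argument("--alpha", type=float, default=0.05)
args = parser.parse_args()

out = Path(args.out_dir)
matched = read_cohort_csv(out / "matched_cohort.csv")
model = fit_classifier(matched, alpha=args.alpha)
for tag, net, label in (("healthy", model.net_healthy, 0),
                        ("schizophrenia", model.net_schiz, 1)):
    save_network(net, out / f"net_{tag}.json")
    strengths = arc_strength(net.dag, matched.stratum(label).profiles)
    dag_to_graphml(net.dag, out / f"net_{tag}.graphml", strengths)
    print(f"{tag}: {len(net.dag.arcs)} arcs")
save_model(model, out / "model.json")
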