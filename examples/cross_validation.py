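"""Assess the target classifier with repeated 2-fold cross-validation.

Per repeat, the validated targets plus an equal-sized fresh random draw of
candidate genes are shuffled and split in half; each half trains a model
that is evaluated on the other.  Recall is the fraction of validation
targets with posterior >= 0.5; the rank-sums Z compares validation-target
posteriors against the random draws (Z > 0 means targets score higher).
"""

import phylofoot as pf

cfg = pf.SimConfig(
    n_species=4, n_genes=600, positive_fraction=0.08, conservation_prob=0.9, seed=5
)
world = pf.generate_world(cfg, pf.demo_motifs(1))
scan = pf.scan_world(world)
reports = pf.run_cross_validation(
    world.targets, scan.feature_table, ("gaussian_process", "logistic"),
    repeats=10, seed=5,
)

for kind, report in reports.items():
    print(f"{kind}: median recall = {report.median_recall:.2f}, "
          f"median rank-sums Z = {report.median_z:.2f}")
print(
    "\nA median recall near 1 and Z well above 3 mean the conserved-site "
    "features cleanly separate planted targets from random candidate genes."
)
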