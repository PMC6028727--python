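"""Generate a synthetic benchmark suite and inspect its structure.

The default seven-dataset suite mimics real label-free benchmark studies:
two replicate groups per dataset, total sample counts from 6 to 116,
log-normal intensities with per-sample scaling biases, and a mixture of
intensity-dependent (MNAR) and random (MCAR) missingness.
"""

import swathbench as sb

tables = sb.generate_benchmark_suite(7, seed=1, n_proteins=500)

print(f"{'dataset':8s} {'proteins':>8s} {'samples':>7s} {'groups':>6s} {'missing':>8s}")
for t in tables:
    missing = t.missing_mask.mean()
    print(f"{t.dataset_id:8s} {t.n_proteins:8d} {t.n_samples:7d} "
          f"{len(set(t.groups.values())):6d} {missing:8.1%}")

# Each row: one dataset. "missing" is the realized fraction of unobserved
# cells -- mostly low-abundance proteins, because the dropout mechanism is
# logistic in log-intensity (left-censoring), plus a small random floor.
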