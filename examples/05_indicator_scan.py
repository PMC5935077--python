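"""Indicator-OTU scan: recover planted environment-responsive OTUs.

Under calibration conditions (no region structure, full 90-sample design)
five planted indicators respond log-linearly to the environmental change
each transplant experienced.  The scan regresses every prevalent OTU's
per-sample share of its own total abundance on those directional deltas
and applies a Bonferroni-corrected threshold.
"""

import marshtransplant as mt
from marshtransplant.simulate import scan_calibration_config

cfg = scan_calibration_config(seed=5)
table, metadata, sites, truth = mt.simulate_experiment(cfg)
table, _ = mt.remove_singletons(table)

summary = mt.run_scan(table, metadata, sites)
print(f"{summary.n_otus_tested} prevalent OTUs x {summary.n_variables} variables "
      f"= {summary.n_tests} regressions")
print(f"Bonferroni-corrected alpha = {summary.alpha} / {summary.n_tests} "
      f"= {summary.corrected_alpha:.2e}")
print(f"passes: {summary.n_passes}\n")

planted = {(f"OTU{i.otu_index:04d}", i.variable): i.beta for i in truth.indicators}
print(f"{'otu':10} {'variable':16} {'slope':>8} {'R^2':>6} {'p':>10}  planted?")
for r in summary.results[:8]:
    mark = f"yes (beta={planted[(r.otu_id, r.variable)]:+.2f})" \
        if (r.otu_id, r.variable) in planted else ""
    print(f"{r.otu_id:10} {r.variable:16} {r.slope:8.3f} {r.r_squared:6.2f} "
          f"{r.p_value:10.1e}  {mark}")
print("\nA negative temperature slope means the OTU loses share when moved to")
print("a warmer site - the pattern reported for the warm-adapted Vibrio OTU.")
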