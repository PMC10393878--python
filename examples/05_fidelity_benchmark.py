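"""Paired fidelity benchmark on a small synthetic cohort.

Each vessel is simulated at two fidelity levels plus a twice-finer
reference arm; accuracy is (1 - |vFFR - vFFR_ref| / vFFR_ref) x 100.
For the full 40-vessel study conditions use default_cohort() and the
canonical five fidelities (several minutes of compute).
"""
from vffrcfd import StenosisSpec, fidelity_sweep

cohort = [
    StenosisSpec(3.0, 45.0, 9.0, 24.5, 30.0, case_id="c45"),
    StenosisSpec(3.4, 60.0, 10.0, 24.0, 30.0, case_id="c60"),
    StenosisSpec(2.8, 70.0, 9.0, 25.0, 30.0, case_id="c70"),
]
sweep = fidelity_sweep(cohort, fidelities=(10, 100))
print(sweep.summary[["fidelity_percent", "median_duration_s",
                     "median_accuracy_pct"]].to_string(index=False))
for pct, conc in sweep.concordance.items():
    print(f"fidelity {pct}%: {conc.percent:.0f}% treat/defer concordance "
          f"at vFFR <= {conc.threshold}")
# Higher fidelity costs more solver time and tracks the reference more
# closely; the treat/defer decision should agree across arms.
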