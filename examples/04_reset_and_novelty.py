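"""Voluntary reset, priming, interference and masking.

Two protocols: (i) repeated same-shape pulses followed by a global
inhibition (GI) pulse that wipes the trace faster the stronger it is;
(ii) a different-shape pulse that erases the old trace (masking) while the
old trace weakens the new one (proactive interference).
"""
import canoncircuit as cc
from canoncircuit.experiments import run_fig5_novelty, run_fig5_reset

p = cc.reference_params()

r = run_fig5_reset(p, gi_strengths=(0.0, 0.3, 0.35, 0.45), dt=1e-3)
print("== repeat + global-inhibition reset ==")
print(f"transient to 1st pulse: {r.transient_first:.3f} SU; "
      f"to 2nd pulse: {r.transient_second:.3f} (repetition suppression)")
print(f"maintained after 1st: {r.maintained_after_first:+.3f}; "
      f"after 2nd: {r.maintained_after_second:+.3f} (priming)")
for g, t in sorted(r.reset_time.items()):
    print(f"GI strength {g}: time to return to baseline after GI = {t} s")

n = run_fig5_novelty(p, dt=1e-3)
print("\n== novel (different-shape) input ==")
print(f"old trace after new input: {n.a_after_b:+.3f} SU vs baseline (masking)")
print(f"new-input memory with old trace present: {n.maintained_b_with_prior_a:+.3f}")
print(f"new-input memory alone:                  {n.maintained_b_alone:+.3f} "
      "(proactive interference)")
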