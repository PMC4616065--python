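"""Reflexive spatial attention: facilitation then inhibition of return.

Two identical location subnetworks; a cue flashes at the target's location
or at the other location, and after a cue-target onset asynchrony (CTOA)
the target appears.  The cueing effect is the target-evoked peak with a
same-location cue minus the peak with an other-location cue: positive =
facilitation, negative = inhibition of return (IOR).
"""
import canoncircuit as cc
from canoncircuit.experiments import run_cueing

res = run_cueing(cc.reference_params(), dt=1e-3)
print("CTOA (s)   cueing effect (SU)")
for c in res.ctoa:
    print(f"  {c:5.2f}    {res.cueing_effect[c]:+8.4f}")
print(f"\nsign changes along the curve: {res.sign_changes}")
print("Facilitation at short CTOAs turns into IOR at long CTOAs - the "
      "bimodal time course of reflexive spatial attention.")
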