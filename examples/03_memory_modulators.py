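"""What modulates the memory: inhibition strength, adaptation, baseline drive.

Runs the three standard parameter sweeps and prints the summary tables
(one row per parameter value; maintained values are relative to baseline).
"""
import canoncircuit as cc
from canoncircuit.experiments import run_fig2, run_fig3, run_fig4

p = cc.reference_params()
fmt = dict(index=False, float_format=lambda x: f"{x:.3f}")

df = run_fig2(p, values=[0.40, 0.45, 0.50, 0.55, 0.60], dt=1e-3)
print("== mutual inhibition (W_inh) ==")
print(df.to_string(**fmt))
print("memory grows sharply with W_inh and the regime flips to 'dual' "
      "past the critical value\n")

df = run_fig3(p, dt=1e-3)
print("== excitatory-synapse adaptation (eta_exc) ==")
print(df.to_string(**fmt))
print("more repetition suppression = weaker maintained activity\n")

df = run_fig4(p, values=[0.0, 0.25, 0.5, 0.75, 0.95, 1.0, 1.25], dt=1e-3)
print("== tonic baseline drive (R) ==")
print(df.to_string(**fmt))
print("no long-term memory without baseline activity (row R=0), and a "
      "minimum R is needed for the single regime")
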