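"""Operating regimes and the critical mutual-inhibition strength.

Classifies the network at three inhibitory weights, then bisects the
single/dual boundary.  In the single regime the baseline is the unique
stable state and memories decay; in the dual regime a second stable
fixed point with elevated activity exists and traces persist forever.
"""
import canoncircuit as cc

params = cc.reference_params()

for W in (0.4, 0.55, 0.7):
    net = cc.build_network(params.replace(W_inh=W))
    print(f"W_inh = {W}: {cc.classify_regime(net)} equilibrium regime")

net = cc.build_network(params)
crit = cc.critical_parameter(net, "W_inh", 0.4, 0.8, tol=1e-3)
print(f"\ncritical W_inh (bisection): {crit:.4f}")
print("Between the last 'single' and first 'dual' value above, maintained")
print("activity stops decaying and becomes self-sustaining.")
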