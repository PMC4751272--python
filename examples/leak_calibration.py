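"""Calibrate the leak reversal potential of each membrane class.

The leak term g_l(V − E_l) is the bookkeeping device that makes the
resting potential an exact equilibrium: E_l is solved from the condition
that potassium, sodium and leak currents sum to zero at V_rest with the
gates at their resting steady state.
"""

from cablenet.membrane import TABLE_NETWORK_SPEC, calibrate_leak_reversal

for region in ("axon", "soma", "dendrite"):
    E_l = calibrate_leak_reversal(TABLE_NETWORK_SPEC, region)
    print(f"{region:9s} E_l = {E_l:.9f} V")

print("\nA membrane initialised at V_rest = -65 mV with these reversals "
      "carries zero net current, so a cell rests indefinitely.")
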