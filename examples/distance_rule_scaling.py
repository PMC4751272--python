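"""How the synapse count scales with the creation distance.

On a box of meandering neurites at roughly uniform length density, the
number of axon-dendrite section pairs closer than dist_synapse grows
like the volume of the search sphere — cubically in the threshold.
"""

from cablenet.experiments import run_synaptogenesis_scaling

table, slope = run_synaptogenesis_scaling(seed=0)
print(table.to_string(index=False))
print(f"log-log slope: {slope:.2f}  (search-sphere volume predicts 3)")
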