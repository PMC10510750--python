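"""Build an atom-mapped network and decompose it into EMU subnetworks.

The network is the bundled five-reaction exemplar: substrate A feeds B,
which is cleaved (v3), condensed with its own cleavage product (v4), and
reversibly interconverted with D (v2); F is the excreted product.  The EMU
decomposition walks backward from the measured fragment F_123 and keeps
only the atom subsets that can influence its labeling.
"""

from emuflux import decompose_network, validate_network
from emuflux.fixtures import toynet1

spec = toynet1()
net = spec.network
print(net)
print(validate_network(net))

emunet = decompose_network(net, ["F_123"])
print(f"\nEMU subnetworks by size: { {s: len(r) for s, r in emunet.by_size.items()} }")
print(emunet.to_dataframe().to_string(index=False))

# Every row is one labeled-carbon transfer: its target EMU receives the
# (convolved) MDV of its sources in proportion to the carrying flux.  Two
# sources on one row (e.g. "B_23 + C_1") mark a condensation node whose MDV
# is the convolution of the source MDVs.
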