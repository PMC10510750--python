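"""MDV algebra: convolution, tracer MDVs, and measurement corrections.

Shows the two corrections applied to raw GC/LC-MS fragment measurements
before fitting: removal of natural heavy-isotope abundance contributed by
the fragment's non-tracer atoms (H, N, O, Si, non-backbone C), and removal
of the unlabeled biomass fraction carried over from the inoculum.
"""

import numpy as np

from emuflux import (MDV, CorrectionSpec, correct_for_inoculum,
                     correct_for_natural_abundance, conv, get_natural_MDV,
                     get_substrate_MDV)
from emuflux.mdv import correction_matrix

# convolution = the mass distribution of a condensation product
a = MDV([0.5, 0.5])
print("conv([0.5,0.5], [0.5,0.5]) =", (a * a).values)   # binomial [.25,.5,.25]

# tracer MDV of glucose atoms 1-2 under an 80/20 [1-13C]/[U-13C] mixture
m = get_substrate_MDV([1, 2], [("100000", 0.8, 1.0), ("111111", 0.2, 1.0)])
print("Glc_12 under 80/20 tracer  =", m.values.round(4))

# natural-abundance correction of a derivatized 3-carbon fragment
true = MDV([0.15, 0.45, 0.25, 0.15])
spec = CorrectionSpec(tracer_atoms=3,
                      elemental_formula={"C": 6, "H": 26, "O": 2, "Si": 2})
raw = correction_matrix(3, spec.elemental_formula) @ true.values
rec = correct_for_natural_abundance(raw, spec)
print("correction round-trip error =",
      float(np.abs(rec.values - true.values).max()))

# inoculum correction: 20% of the sampled biomass never saw tracer
nat = get_natural_MDV(3)
raw2 = 0.2 * nat.values + 0.8 * true.values
print("inoculum-corrected          =",
      correct_for_inoculum(raw2, 0.2).values.round(4),
      "(should equal", true.values.round(4), ")")
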