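"""Steady-state auxin under the five ABCB-PIN interaction scenarios.

Prints the relative elongation-zone (EZ) epidermis+cortex auxin and the mean
absolute cell-pair flux per scenario.  Outer-EZ accumulation requires an
ABCB-independent efflux (scenarios I, III, IV); fluxes are smallest when the
carriers are fully independent (I) and largest when ABCB efflux needs PIN
(II, V).
"""

import numpy as np
import rootflux as rf
from rootflux.model import flux_field

template = rf.generate_regular_template()
dist = rf.build_distribution(template)
ez = [c.id for c in template.cells.values()
      if c.cell_type in ("epidermis", "cortex") and c.zone == "EZ"]

for sid in ["I", "II", "III", "IV", "V"]:
    system, x = rf.simulate_genotype(template, rf.scenario(sid), dist=dist)
    rel = np.mean([x[system.cell_index[i]] for i in ez]) / np.mean(
        [x[system.cell_index[c]] for c in template.cells])
    ff = flux_field(x, system)
    mag = np.mean(np.abs(list(ff.cell_pair.values())))
    print(f"scenario {sid}: relative EZ auxin {rel:5.2f}   mean |flux| {mag:.3f}")
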