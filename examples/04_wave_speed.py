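"""Auxin wave speeds in the reduced single-cell-file model.

Cell 0 is clamped at concentration 1; PINs sit on the distal end of every
cell, ABCBs on both ends, and the co-dependent component where they
co-occur.  The front speed grows with the polar efflux and is retarded by
the nonpolar ABCB component, so the purely polar scenarios (II, V) are the
fastest for their polar strength.
"""

import numpy as np
import rootflux as rf
from rootflux.cellfile import CellFileModel, simulate_file, wave_speed

frames = np.linspace(0, 1800, 61)
for sid in ["I", "II", "III", "IV", "V"]:
    prof = simulate_file(CellFileModel(scenario=rf.scenario(sid)), 1800.0, frames)
    ft = wave_speed(prof)
    print(f"scenario {sid}: wave speed {ft.speed:.3f} um/s (fit R^2 {ft.r_squared:.4f})")
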