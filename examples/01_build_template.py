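"""Build the geometrically regular root-tip template and save it as JSON.

The template is a 2D longitudinal section: mirrored tissue files (epidermis,
cortex, endodermis, pericycle) around a central stele, a 210-um meristem, a
quiescent centre at the origin, three columella tiers below it and lateral
root cap files flanking the meristem.
"""

import rootflux as rf

template = rf.generate_regular_template()
rf.write_template(template, "template.json")

zones = {}
for cell in template.cells.values():
    zones[cell.zone] = zones.get(cell.zone, 0) + 1
print(f"{len(template.cells)} cells, {len(template.walls)} walls, "
      f"{len(template.membrane_segments)} membrane segments")
print(f"zone counts (None = root cap): {zones}")
# Zone counts tell you how many cells sit in the meristem (MZ) vs the
# elongation zone (EZ); cap cells carry no zone.
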