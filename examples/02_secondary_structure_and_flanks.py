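"""Classify helix/sheet/other from backbone dihedrals and label flanks.

A chain with a helical stretch embedded in coil is assigned H/S/O
labels from its (phi, psi) windows; the element's three upstream and
three downstream residues receive the H-3..H+3 flank offsets used when
pooling dihedral statistics by position.
"""

import rotormat as rm

pairs = [(70.0, 60.0)] * 4 + [(-60.0, -45.0)] * 6 + [(70.0, 60.0)] * 4
records = [rm.RotorRecord("A", "A", i, phi=p, psi=s) for i, (p, s) in enumerate(pairs)]

labels = rm.assign_secondary_structure(records)
elements = rm.segment_elements(labels)
flanks = rm.label_flanks(elements, len(records))

print("labels:  ", "".join(labels))
print("elements:", elements)
for idx in sorted(flanks):
    tags = ", ".join(f"{k}{o:+d}" if o else k for k, o in sorted(flanks[idx]))
    print(f"  residue {idx:2d}: {tags}")

print(
    "\nThe six helical residues form one element (offset 0); residues"
    " 1-3 carry the entering offsets H-3..H-1 and residues 10-12 the"
    " leaving offsets H+1..H+3."
)
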