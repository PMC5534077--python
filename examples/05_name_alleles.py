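"""Name called alleles against a reference set.

An allele identical to a reference at full length keeps the reference
name; 100% identity over the overlap but different length appends 'a';
anything else is novel and numbered (Pado-UA*NNN style).
"""

import mhcdoc as m

pool = m.make_allele_pool(6, 0, seed=5)
sequences = [a.sequence for a in pool.classical]

# pretend the first three alleles are previously published
reference = [(f"Pado-UA*10{i}", seq) for i, seq in enumerate(sequences[:3], 1)]
# one called allele is a length variant of a published one
called = sequences[1:5] + [sequences[0][:-2]]

names = m.name_alleles(called, reference, prefix="Pado-UA*", start_number=396)
for seq in called:
    an = names[seq]
    print(f"{an.assigned_name:14s} {an.status:20s} ({len(seq)} bp)")

# Known alleles keep their published names, the truncated copy becomes
# Pado-UA*101a, and the two unseen sequences get fresh numbers starting
# at Pado-UA*396.
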