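"""Absolute move strings: compact text encoding of lattice structures.

Every neighbour vector gets a letter (A, B, C, ... in lexicographic vector
order); a chain of l nodes becomes l-1 letters.  Decoding reproduces the
structure up to translation, and validity (self-avoidance) is re-checked.
"""

import latticefit as lf

lat = lf.make_lattice("CUB")
print("CUB alphabet:")
for vec, tok in lat.alphabet().items():
    print(f"  {tok} = {vec}")

m = lf.random_structure(lf.FixtureSpec("CUB", 10, lf.BACKBONE, seed=5))
ms = lf.encode_move_string(m, lat)
print(f"\n10-residue structure -> '{ms.backbone}' ({len(ms.backbone)} tokens)")

decoded = lf.decode_move_string(ms, lat)
print(f"decode(encode(m)) == m up to translation: {decoded == m.translated(-m.backbone[0])}")

try:
    lf.decode_move_string("AB" + lat.alphabet()[(-1, 0, 0)] * 2, lat)
except lf.InvalidStructureError as exc:
    print(f"self-colliding string rejected: {exc}")
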