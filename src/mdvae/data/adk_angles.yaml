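# Domain-angle collective variables for E. coli adenylate kinase.
# Each vector runs from the centroid of its tail residue ranges to the
# centroid of its head ranges (inclusive intervals).  Keys give the
# crystal-structure numbering the residue ids refer to.
1ake-4ake:
  core-nmp:
    vector1: {tail: [[90, 99]], head: [[35, 55]]}
    vector2: {tail: [[90, 99]], head: [[115, 125]]}
  core-lid:
    vector1: {tail: [[115, 125]], head: [[179, 185]]}
    vector2: {tail: [[115, 125]], head: [[125, 153]]}
1dvr:
  core-nmp:
    vector1: {tail: [[95, 101], [106, 108]], head: [[39, 59]]}
    vector2: {tail: [[95, 101], [106, 108]], head: [[124, 134]]}
  core-lid:
    vector1: {tail: [[124, 134]], head: [[188, 194]]}
    vector2: {tail: [[124, 134]], head: [[134, 162]]}
2ak3:
  core-nmp:
    vector1: {tail: [[95, 104]], head: [[41, 61]]}
    vector2: {tail: [[95, 104]], head: [[119, 129]]}
  core-lid:
    vector1: {tail: [[119, 129]], head: [[183, 189]]}
    vector2: {tail: [[119, 129]], head: [[129, 157]]}
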