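"""Render a consensus string from aligned junction boxes.

Copies of the conserved 3' box (LTR 3' end + primer binding site) are
sampled with a few mutations, aligned, and rendered with the standard
convention: uppercase = totally conserved (R/Y for a conserved purine or
pyrimidine class), lowercase = 70-100% conserved, dot = below 70%.
"""

import numpy as np

from retrozyme import BoxConsensus, build_consensus, center_star_align
from retrozyme.consensus import column_frequencies

rng = np.random.default_rng(8)
box = BoxConsensus().box3
copies = []
for _ in range(10):
    s = list(box)
    for i in rng.choice(len(s), size=rng.integers(0, 4), replace=False):
        s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
    copies.append("".join(s))

aln = center_star_align(copies)
cons = build_consensus(aln)
for rid, row in zip(aln.ids, aln.rows):
    print(f"{rid:>6}  {row}")
print(f"{'cons':>6}  {cons}")

freqs = column_frequencies(aln)
n_total = sum(c.isupper() for c in cons)
print(f"\n{n_total}/{len(cons)} columns totally conserved; lowercase letters "
      "mark 70-100% conservation, dots fall below 70%.")
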