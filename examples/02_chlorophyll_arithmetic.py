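"""DMF-extract absorbance to leaf chlorophyll content, and back.

A leaf sample's extract reads A647 = 0.2 and A664 = 0.4 on the
spectrophotometer; with the default geometry (4 mL extract, two 0.82 cm^2
discs) this corresponds to about 16.76 µg·cm⁻² of total chlorophyll.  The
inverse map (used by the synthetic generator) fixes the A647:A664 ratio and
round-trips exactly.
"""

from leafspec import absorbance_from_lcc, lcc_from_absorbance

lcc = lcc_from_absorbance(0.2, 0.4)
print(f"A647=0.2, A664=0.4  ->  LCC = {lcc:.3f} ug/cm^2")

for target in (4.0, 10.0, 23.0):
    a647, a664 = absorbance_from_lcc(target)
    back = lcc_from_absorbance(a647, a664)
    print(f"LCC {target:5.1f} -> (A647={a647:.4f}, A664={a664:.4f}) "
          f"-> LCC {back:.12f}")
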