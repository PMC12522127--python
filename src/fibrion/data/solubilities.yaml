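# Room-temperature (~25 C) aqueous solubility limits. These are literature
# convenience defaults for the drying mass balance; override per run when a
# different temperature or buffer applies. Units: mM unless stated.
NaCl: 6100
KCl: 4800
Na2HPO4: 540
NaH2PO4: 7100
K2HPO4: 9200
KH2PO4: 1800
Na2SO4: 1970
MgCl2: 5800
CaCl2: 6700
# protein solubility in Tris buffer, mass units
fibrinogen:
  value: 10
  unit: mg/mL
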