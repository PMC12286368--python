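# Synthetic illustrative permissible limits (mg/kg dry weight) for demos and
# tests. These are placeholders sized against the synthetic generator's
# default concentration scales, NOT actual WHO/FAO or national limit values.
# Replace with a real limits table for any substantive screening.
element,authority,limit_mg_kg
Fe,example-international,15.0
Zn,example-international,25.0
Cu,example-international,3.0
Co,example-international,0.5
Cr,example-international,0.08
V,example-international,0.3
Al,example-international,2.0
Ni,example-international,0.5
As,example-international,0.15
Hg,example-international,0.03
Pb,example-national,0.1
Cd,example-national,0.06
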