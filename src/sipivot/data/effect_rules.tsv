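kind	mode	pos_min	pos_max	site_class	status
none	none	0	0	seed	functional
none	none	0	0	nucleation_bulge	functional
none	none	0	0	perfect_match	functional
dSpacer	substitution	2	7	seed	abolished
dSpacer	substitution	6	6	nucleation_bulge	abolished
dSpacer	substitution	6	6	perfect_match	functional
C3	substitution	6	6	seed	abolished
C3	substitution	6	6	nucleation_bulge	abolished
C3	substitution	6	6	perfect_match	functional
rSpacer	substitution	3	6	seed	abolished
rSpacer	substitution	3	6	perfect_match	attenuated
dSpacer	insertion	4	6	seed	abolished
dSpacer	insertion	4	6	perfect_match	attenuated
rSpacer	insertion	4	6	seed	abolished
rSpacer	insertion	4	6	perfect_match	attenuated
OMe2	substitution	2	2	seed	attenuated
OMe2	substitution	2	2	nucleation_bulge	attenuated
UNA	substitution	7	7	seed	attenuated
2bulge	duplex	2	2	seed	attenuated
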