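# Synthetic representative dinucleotide stiffness table (diagonal force constants).
# This is NOT a published molecular-dynamics parameter set: it is a stand-in with
# channel magnitudes in the ranges typical of MD-derived dinucleotide constants,
# shipped so the toolkit runs out of the box. For real analyses, supply your own
# MD-derived table in this format (it is completed/validated on load).
# Units: twist/tilt/roll in kcal/(mol*deg^2); shift/slide/rise in kcal/(mol*A^2).
# Only the 10 unique steps are listed; the loader completes the 16 by
# reverse-complement symmetry. Channel order is canonical for the package.
step	twist	tilt	roll	shift	slide	rise
AA	0.0280	0.0380	0.0200	1.72	2.10	3.40
AC	0.0360	0.0420	0.0240	1.35	2.60	3.90
AG	0.0310	0.0400	0.0215	1.50	2.25	3.55
AT	0.0390	0.0460	0.0260	1.15	2.85	4.20
CA	0.0210	0.0330	0.0165	1.60	1.55	2.90
CC	0.0330	0.0410	0.0230	1.45	2.40	3.70
CG	0.0230	0.0345	0.0175	1.55	1.70	3.05
GA	0.0300	0.0395	0.0210	1.48	2.20	3.50
GC	0.0400	0.0470	0.0270	1.20	2.95	4.30
TA	0.0180	0.0310	0.0150	1.65	1.40	2.75
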