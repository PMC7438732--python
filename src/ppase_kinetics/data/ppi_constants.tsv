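# Default stepwise dissociation constants for pyrophosphate complexes, in mM.
# Conditional constants at typical assay ionic strength (~0.1-0.2 M, 25 C),
# taken from a standard PPi-complexation compilation.  Protonation steps are
# given as pKa (molar scale) and converted via Kd[mM] = 10**(3 - pKa).
# Override with --constants / ComplexationConstants.from_table for
# assay-specific values.
species	kd_mM	pka
HPPi		8.94
H2PPi		6.13
MgPPi	0.004
Mg2PPi	2.5
MgHPPi	0.8
KPPi	12.0
NaPPi	11.0
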