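# Synthetic aerobic-glycolysis network (J=17, I=20): multi-step lumped
# reactions r2/r4/r5/r12/r16/r20 (hexose monophosphate shunt, glycolysis,
# TCA cycle, oxaloacetate-malate shuttle, Cori cycle), transport reactions
# r8 (pyruvate), r14 (citrate), r17 (mitochondrial PEP); _m/_c suffixes mark
# mitochondrial/cytosolic species.  The lumped integer coefficients are this
# package's own reconstruction of the pathway topology, not curated values.
species,r1,r2,r3,r4,r5,r6,r7,r8,r9,r10,r11,r12,r13,r14,r15,r16,r17,r18,r19,r20
glucose_c,-1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1
glucose6P_c,1,-1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
ribulose5P_c,0,1,0,-3,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
glyceraldehyde3P_c,0,0,0,5,-1,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0
pep_c,0,0,1,0,1,-1,0,0,0,0,0,0,0,0,0,0,1,0,0,0
pyruvate_c,0,0,0,0,0,1,-1,-1,0,0,0,0,0,0,0,0,0,0,0,0
lactate_c,0,0,0,0,0,0,1,0,0,0,0,0,0,0,0,0,0,0,0,-2
pyruvate_m,0,0,0,0,0,0,0,1,-1,-1,0,0,0,0,0,0,0,0,0,0
acetylCoA_m,0,0,0,0,0,0,0,0,1,0,-1,0,0,0,0,0,0,0,0,0
oxaloacetate_m,0,0,0,0,0,0,0,0,0,1,-1,1,-1,0,0,-1,0,0,0,0
citrate_m,0,0,0,0,0,0,0,0,0,0,1,-1,0,-1,0,0,0,0,0,0
citrate_c,0,0,0,0,0,0,0,0,0,0,0,0,0,1,-1,0,0,0,0,0
malate_m,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,0,-1,0,0
malate_c,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,0,1,-1,0
oxaloacetate_c,0,0,-1,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,1,0
pep_m,0,0,0,0,0,0,0,0,0,0,0,0,1,0,0,0,-1,0,0,0
co2_m,0,0,0,0,0,0,0,0,1,-1,0,2,1,0,0,0,0,0,0,0
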