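# Van Walraven integer weights for the 30 Elixhauser categories (hypertension
# combined). Sum of positive weights = 89, sum of negative weights = -19, the
# attainable range of the weighted score. version=vw-v1
# category	weight
chf	7
arrhythmia	5
valvular	-1
pulm_circ	4
pvd	2
htn	0
paralysis	7
neuro_other	6
chronic_pulm	3
dm_uncomp	0
dm_comp	0
hypothyroid	0
renal_fail	5
liver	11
pud	0
hiv	0
lymphoma	9
mets	12
tumor	4
rheum	0
coag	3
obesity	-4
wtloss	6
fluid_elec	5
anemia_bl	-2
anemia_def	-2
alcohol	0
drug	-7
psychoses	0
depression	-3
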