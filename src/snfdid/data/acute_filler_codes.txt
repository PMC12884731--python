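# Acute / non-comorbidity ICD-10-CM codes used as filler diagnoses by the
# synthetic claims generator. None of these codes matches any Elixhauser
# category prefix, so diagnosis count and comorbidity score can be calibrated
# independently. A unit test enforces the no-match property.
A419
B9620
D649
G4700
H539
I959
J069
J189
J960
K219
K5900
L298
L89159
M1990
M2550
M549
M6281
N179
N390
R0902
R110
R1310
R268
R296
R339
R410
R4182
R509
R531
R600
S0090XA
T148XXA
W1930XA
Z5189
Z740
Z779
Z8673
Z87891
Z9181
Z993
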