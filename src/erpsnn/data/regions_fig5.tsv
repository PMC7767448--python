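label	site	hemisphere
FP1	frontal	left
FPZ	frontal	midline
FP2	frontal	right
AF3	frontal	left
AF4	frontal	right
F7	temporal	left
F5	frontal	left
F3	frontal	left
F1	frontal	left
FZ	frontal	midline
F2	frontal	right
F4	frontal	right
F6	frontal	right
F8	temporal	right
FT7	temporal	left
FC5	frontocentral	left
FC3	frontocentral	left
FC1	frontocentral	left
FCZ	frontocentral	midline
FC2	frontocentral	right
FC4	frontocentral	right
FC6	frontocentral	right
FT8	temporal	right
T7	temporal	left
C5	frontocentral	left
C3	frontocentral	left
C1	frontocentral	left
CZ	frontocentral	midline
C2	frontocentral	right
C4	frontocentral	right
C6	frontocentral	right
T8	temporal	right
TP7	temporal	left
CP5	centroparietal	left
CP3	centroparietal	left
CP1	centroparietal	left
CPZ	centroparietal	midline
CP2	centroparietal	right
CP4	centroparietal	right
CP6	centroparietal	right
TP8	temporal	right
P7	centroparietal	left
P5	centroparietal	left
P3	centroparietal	left
P1	centroparietal	left
PZ	centroparietal	midline
P2	centroparietal	right
P4	centroparietal	right
P6	centroparietal	right
P8	centroparietal	right
PO7	occipitoparietal	left
PO5	occipitoparietal	left
PO3	occipitoparietal	left
POZ	occipitoparietal	midline
PO4	occipitoparietal	right
PO6	occipitoparietal	right
PO8	occipitoparietal	right
CB1	occipitoparietal	left
O1	occipitoparietal	left
OZ	occipitoparietal	midline
O2	occipitoparietal	right
CB2	occipitoparietal	right
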