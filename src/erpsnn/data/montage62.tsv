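label	x_mm	y_mm	z_mm
FP1	-29.44	83.92	-6.99
FPZ	0.11	88.25	-1.71
FP2	29.87	84.90	-7.08
AF3	-33.70	76.84	21.23
AF4	35.71	77.73	21.96
F7	-70.26	42.47	-11.42
F5	-64.47	48.04	16.92
F3	-50.24	53.11	42.19
F1	-27.50	56.93	60.34
FZ	0.31	58.51	66.46
F2	29.51	57.60	59.54
F4	51.84	54.30	40.81
F6	67.91	49.83	16.37
F8	73.04	44.42	-12.00
FT7	-80.78	14.12	-11.13
FC5	-77.21	18.64	24.46
FC3	-60.18	22.72	55.54
FC1	-34.06	26.01	79.99
FCZ	0.38	27.39	88.67
FC2	34.78	26.44	78.81
FC4	62.29	23.72	55.63
FC6	79.53	19.94	24.44
FT8	81.82	15.42	-11.33
T7	-84.16	-16.02	-9.35
C5	-80.28	-13.76	29.16
C3	-65.36	-11.63	64.36
C1	-36.16	-9.98	89.75
CZ	0.40	-9.17	100.24
C2	37.67	-9.62	88.41
C4	67.12	-10.90	63.58
C6	83.46	-12.78	29.21
T8	85.08	-15.02	-9.49
TP7	-84.83	-46.02	-7.06
CP5	-79.59	-46.55	30.95
CP3	-63.56	-47.01	65.62
CP1	-35.51	-47.29	91.31
CPZ	0.39	-47.32	99.43
CP2	38.38	-47.07	90.69
CP4	66.61	-46.64	65.58
CP6	83.32	-46.10	31.21
TP8	85.55	-45.55	-7.13
P7	-72.43	-73.45	-2.49
P5	-67.27	-76.29	28.38
P3	-53.01	-78.79	55.94
P1	-28.62	-80.52	75.44
PZ	0.32	-81.11	82.61
P2	31.92	-80.49	76.72
P4	55.67	-78.56	56.56
P6	67.89	-75.90	28.09
P8	73.06	-73.07	-2.54
PO7	-54.84	-97.53	2.79
PO5	-48.42	-99.34	21.60
PO3	-36.51	-100.85	37.17
POZ	0.22	-102.18	50.61
PO4	36.78	-100.85	36.40
PO6	49.82	-99.45	21.73
PO8	55.67	-97.63	2.73
CB1	-54.91	-98.04	-35.47
O1	-29.41	-112.45	8.84
OZ	0.11	-114.89	14.66
O2	29.84	-112.16	8.80
CB2	54.99	-98.09	-35.54
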