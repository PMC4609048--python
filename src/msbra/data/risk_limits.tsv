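effect	outcome	low_pct	high_pct	onset_exempt	high_from_low
Acute severe allergy	DEATH	0.24	0.00	no	yes
Acute severe allergy	LIFE_THREATENING	2.65	1.18	no	no
Cardio-pulmonary distress	DEATH	0.33	0.79	no	no
Cardio-pulmonary distress	PERSISTENT	0.02	0.39	no	no
Cardio-pulmonary distress	LIFE_THREATENING	0.86	1.71	no	no
Diabetes	DEATH	0.02	0.53	no	no
Diabetes	PERSISTENT	0.86	1.05	no	no
Diabetes	LIFE_THREATENING	0.07	0.13	no	no
Gastrointestinal haemorrhage	DEATH	0.26	0.39	no	no
Gastrointestinal haemorrhage	PERSISTENT	0.13	0.13	no	no
Gastrointestinal haemorrhage	LIFE_THREATENING	0.37	0.79	no	no
Hepatotoxicity	DEATH	0.11	0.13	no	no
Hepatotoxicity	PERSISTENT	0.11	0.53	no	no
Hepatotoxicity	LIFE_THREATENING	0.29	0.66	no	no
Myopathy	PERSISTENT	0.46	0.79	no	no
Myopathy	LIFE_THREATENING	0.07	0.13	no	no
Osteonecrosis	PERSISTENT	0.57	1.58	yes	no
Pancreatitis	DEATH	0.04	0.13	no	no
Psychosis	PERSISTENT	0.04	0.13	no	no
Psychosis	LIFE_THREATENING	0.07	0.13	no	no
Seizure	DEATH	0.09	0.39	no	no
Seizure	PERSISTENT	0.13	0.00	no	yes
Seizure	LIFE_THREATENING	0.13	0.13	no	no
Ventricular arrhythmia/cardiac arrest	DEATH	0.55	1.05	no	no
Ventricular arrhythmia/cardiac arrest	PERSISTENT	0.09	0.13	no	no
Ventricular arrhythmia/cardiac arrest	LIFE_THREATENING	0.86	1.18	no	no
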