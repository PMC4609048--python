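effect	death	persistent	life_threatening
Acute severe allergy	yes	no	yes
Cardio-pulmonary distress	yes	yes	yes
Diabetes	yes	yes	yes
Gastrointestinal haemorrhage	yes	yes	yes
Hepatotoxicity	yes	yes	yes
Myopathy	no	yes	yes
Osteonecrosis	no	yes	no
Pancreatitis	yes	no	no
Psychosis	no	yes	yes
Seizure	yes	yes	yes
Ventricular arrhythmia/cardiac arrest	yes	yes	yes
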