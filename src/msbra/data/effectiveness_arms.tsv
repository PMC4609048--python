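alternative	study	cumulative_dose_mg	route	duration_days	assessment_day	successes	size
HIGH_DOSE	Durelli 1986	7035	IV	15	15	10	11
HIGH_DOSE	Milligan 1987	2500	IV	5	28	10	13
HIGH_DOSE	La Mantia 1994	5750	IV	14	14	8	10
HIGH_DOSE	Barnes 1997	3000	IV	3	28	13	38
HIGH_DOSE	Sellebjerg 1998	3676	PO	15	21	14	26
HIGH_DOSE	Visser 2004	2500	IV	5	28	6	9
HIGH_DOSE	Ramo-Tello 2013	3000	IV	3	28	15	23
HIGH_DOSE	Ramo-Tello 2013	3750	PO	3	28	15	22
LOW_DOSE	Milanese 1989	390	IV	14	30	3	10
LOW_DOSE	La Mantia 1994	390	IV	14	14	6	10
LOW_DOSE	Barnes 1997	588	PO	21	28	20	42
PLACEBO	Miller 1961	0	IM	21	21	4	18
PLACEBO	Rose 1970	0	IM	14	28	39.25	94
PLACEBO	Durelli 1986	0	IV	15	15	4	10
PLACEBO	Milligan 1987	0	IV	5	28	2	9
PLACEBO	Sellebjerg 1998	0	PO	15	21	6	25
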