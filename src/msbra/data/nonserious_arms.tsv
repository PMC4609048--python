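alternative	study	cumulative_dose_mg	route	duration_days	followup_days	successes	size
HIGH_DOSE	Abbruzzese 1983	8400	IV	15	NA	3	30
HIGH_DOSE	Durelli 1986	7035	IV	15	15	9.2	13
HIGH_DOSE	Thompson 1989	3000	IV	3	84	1	29
HIGH_DOSE	Sellebjerg 1998	3676	PO	15	56	23	26
HIGH_DOSE	La Mantia 1994	5750	IV	14	14	0	10
HIGH_DOSE	Soelberg-Sorensen 2004	3000	IV	3	182	30	40
HIGH_DOSE	Martinelli 2009	5000	IV	5	28	11	20
HIGH_DOSE	Martinelli 2009	5000	PO	5	28	15	20
HIGH_DOSE	Ramo-Tello 2013	3000	IV	3	28	24	24
HIGH_DOSE	Ramo-Tello 2013	3750	PO	3	28	24	25
HIGH_DOSE	Shaygannejad 2013	3000-5000+taper	IV	13-20	90	58	64
PLACEBO	Rose 1970	0	IM	14	28	8	94
PLACEBO	Durelli 1986	0	IV	15	15	5.0	10
PLACEBO	Sellebjerg 1998	0	PO	15	56	8	25
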