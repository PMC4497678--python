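# Published power-law tail-fit parameters for ten long single-author novels
# (English, Spanish, French, Finnish), words (w) vs lemmas (l).
# Columns: V = vocabulary size, n_m = maximum type frequency, N_a = types in
# the fitted tail, a = lower frequency cutoff, gamma/sigma = ML exponent and
# its standard deviation, two_sigma_d = 2*sqrt(sigma_w^2+sigma_l^2) as
# printed, ell1 = lemmas associated with exactly one word form.
label	V_w	n_mw	N_aw	a_w	gamma_w	sigma_w	V_l	n_ml	N_al	a_l	gamma_l	sigma_l	two_sigma_d	ell1
Clarissa	20492	38632	1514	51	1.83	0.02	9041	41679	838	101	1.83	0.03	0.07	5750
Moby-Dick	18516	14438	2658	8	1.97	0.02	9141	14438	1548	13	1.90	0.02	0.06	6157
Ulysses	29450	14934	4377	6	1.95	0.01	12469	14934	1024	26	1.97	0.03	0.07	8670
Don Quijote	21180	20704	939	40	1.93	0.03	7432	31521	936	32	1.83	0.03	0.08	3812
La Regenta	21871	19596	1196	26	2.01	0.03	9900	32300	993	32	2.00	0.03	0.08	5308
Artamène	25161	88490	936	200	1.86	0.03	5008	119016	641	200	1.79	0.03	0.08	2178
Bragelonne	25775	26848	3173	16	1.84	0.02	10744	45577	1382	40	1.84	0.02	0.06	5391
Seitsemän veljestä	22035	4247	22035	1	2.13	0.01	7658	4247	474	26	2.13	0.05	0.10	4246
Kevät ja takatalvi	25071	5042	8660	2	2.05	0.01	8898	6886	699	20	1.96	0.04	0.07	5060
Vanhempieni romaani	35931	5254	6523	3	2.09	0.01	13510	7526	571	32	2.05	0.04	0.09	7837
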