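# Raw one-sided Fisher P-values per cancer type from a published berberine
# indication screen (18 significant indications), with the printed adjusted
# P (single-step multiplicative correction over 24 tested cancer types), the
# printed -log10(adjusted P), and supporting literature PMIDs (N/A = no
# published validation).
cancer_type	p_raw	adj_p_printed	neglog_printed	pmids
HCC	5.63e-20	1.35e-18	17.87	26081696|25496992|24942805
LUAD	4.52e-10	1.08e-08	7.96	24766860|26672764|26503561
BLCA	4.92e-10	1.18e-08	7.93	21545798|23065570|10418949
CM	5.12e-10	1.23e-08	7.91	N/A
HNSCC	3.03e-09	7.27e-08	7.14	26503508
SQCC	1.82e-07	4.37e-06	5.36	N/A
EC	2.18e-07	5.23e-06	5.28	28465635|26667771|21858113
UCEC	3.03e-07	7.27e-06	5.14	N/A
PRAD	4.77e-07	1.15e-05	4.94	16505103|26698234|25572870
BRCA	5.53e-07	1.33e-05	4.88	29143794|29414799|28926092
CCSK	9.58e-07	2.30e-05	4.64	N/A
CLL	2.28e-05	5.47e-04	3.26	N/A
STAD	7.32e-05	1.76e-03	2.76	27142767|25837881|18468407
SCLC	2.22e-04	5.33e-03	2.27	N/A
NBL	5.36e-04	1.29e-02	1.89	27235712|19189664|19096576
LGG	6.95e-04	1.67e-02	1.78	N/A
CRAC	1.34e-03	3.21e-02	1.49	23604974|26463023|25954974
SOC	1.40e-03	3.36e-02	1.47	N/A
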