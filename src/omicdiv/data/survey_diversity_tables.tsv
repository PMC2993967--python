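# Published per-sample summary statistics from an eight-sample temperate coastal
# multi-omic time series: 16S V6 OTU tables rarefied to 4070 (and,
# for Archaea, also 16771) reads, and pORF cluster tables rarefied to 66529 pORFs.
# richness = observed OTUs / 95%-identity pORF clusters; singletons = features seen
# once; coverage/margalef/evenness as printed (blank where not reported).
assay	sample	depth	richness	singletons	coverage	margalef	evenness
bacteria_16s	jan_day	4070	331	138	96.61	39.7	0.8901
bacteria_16s	jan_night	4070	558	307	92.46	67.02	0.9577
bacteria_16s	apr_day	4070	177	74	98.18	21.18	0.8289
bacteria_16s	apr_night	4070	199	86	97.89	23.82	0.8745
bacteria_16s	aug27_day4pm	4070	189	76	98.13	22.62	0.9355
bacteria_16s	aug27_night10pm	4070	174	67	98.35	20.81	0.9341
bacteria_16s	aug28_night4am	4070	192	87	97.86	22.98	0.9265
bacteria_16s	aug28_day10am	4070	189	83	97.96	22.62	0.9247
bacteria_16s	combined	32560	999	523	98.39		
archaea_16s	jan_day	4070	24	7	99.83	2.767	0.8271
archaea_16s	jan_night	4070	46	20	99.51	5.414	0.798
archaea_16s	aug27_day4pm	4070	14	2	99.95	1.564	0.6347
archaea_16s	aug27_night10pm	4070	13	5	99.88	1.444	0.628
archaea_16s	combined	16280	63	31	99.81		
archaea_16s_deep	jan_day	16771	46	25	99.85		
archaea_16s_deep	jan_night	16771	70	33	99.80		
archaea_16s_deep	aug27_day4pm	16771	22	9	99.95		
archaea_16s_deep	aug27_night10pm	16771	27	14	99.92		
archaea_16s_deep	combined	67084	111	64	99.90		
metagenome_porf	jan_day	66529	56337	52891	20.50		
metagenome_porf	jan_night	66529	64446	63378	4.74		
metagenome_porf	apr_day	66529	61187	58691	11.78		
metagenome_porf	apr_night	66529	59904	57779	13.15		
metagenome_porf	aug27_day4pm	66529	65601	64818	2.57		
metagenome_porf	aug27_night10pm	66529	63032	61068	8.21		
metagenome_porf	aug28_night4am	66529	64729	63359	4.76		
metagenome_porf	aug28_day10am	66529	65075	63945	3.88		
metatranscriptome_porf	jan_day	66529	31026	23038	65.37		
metatranscriptome_porf	jan_night	66529	50354	43687	34.33		
metatranscriptome_porf	apr_day	66529	30334	22394	66.34		
metatranscriptome_porf	apr_night	66529	34217	26840	59.66		
metatranscriptome_porf	aug27_day4pm	66529	24848	17373	73.89		
metatranscriptome_porf	aug27_night10pm	66529	24136	17177	74.18		
metatranscriptome_porf	aug28_night4am	66529	33191	25636	61.47		
metatranscriptome_porf	combined	465703	205368	157658	66.15		
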