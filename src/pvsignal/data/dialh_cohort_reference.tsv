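# Published reference cohort counts for drug-induced autoimmune-like
# hepatitis reports in FAERS, 2004Q1-2024Q1 (N = 5,723 deduplicated reports;
# 8,018 outcome entries, outcomes being multi-valued per report).  Used as a
# desk-check input for the percentage arithmetic of the cohort profiler.
# Columns: variable, level, count, denominator.
variable	level	count	denom
sex	female	3498	5723
sex	male	1641	5723
sex	unknown	584	5723
age	<19	243	5723
age	19~45	999	5723
age	45~65	1860	5723
age	65~75	841	5723
age	>=75	472	5723
age	unknown	1308	5723
reporter	Physician	2520	5723
reporter	Other health-professional	1153	5723
reporter	Consumer	898	5723
reporter	Pharmacist	858	5723
reporter	unknown	266	5723
reporter	Lawyer	27	5723
reporter	Registered Nurse	1	5723
country	other	2931	5723
country	United States	1490	5723
country	Germany	396	5723
country	Japan	321	5723
country	France	318	5723
country	United Kingdom	267	5723
outcome	other serious	4360	8018
outcome	hospitalization	2573	8018
outcome	death	448	8018
outcome	life threatening	404	8018
outcome	disability	186	8018
outcome	required intervention	44	8018
outcome	congenital anomaly	3	8018
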