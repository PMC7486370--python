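arg_id	gene_id	drug_classes	mechanisms	read_count	covered_fraction
ARG001	g001	tetracycline antibiotic	Antibiotic efflux	14	0.900
ARG002	g002	cephamycin	Antibiotic inactivation	22	0.899
ARG003	g003	fluoroquinolone antibiotic	Antibiotic efflux	31	0.950
ARG004	g004	glycopeptide antibiotic	Antibiotic target alteration	9	1.000
ARG005	g005	penam	Antibiotic inactivation	17	0.920
ARG006	g006	macrolide antibiotic	Antibiotic efflux	25	0.910
ARG007	g007	tetracycline antibiotic	Antibiotic target alteration	12	0.930
ARG008	g008	cephamycin	Antibiotic inactivation	40	0.985
ARG009	g009	penam	Antibiotic target replacement	8	0.850
ARG010	g010	tetracycline antibiotic	Antibiotic efflux	19	0.800
ARG011	g011	fluoroquinolone antibiotic	Antibiotic target alteration	5	0.700
ARG012	g012	glycopeptide antibiotic	Antibiotic efflux	11	0.600
ARG013	g013	cephamycin	Antibiotic inactivation	7	0.500
ARG014	g014	penam	Reduced permeability to antibiotic	13	0.400
ARG015	g015	macrolide antibiotic	Antibiotic efflux	21	0.300
ARG016	g016	tetracycline antibiotic	Antibiotic inactivation	6	0.200
ARG017	g017	cephamycin	Antibiotic target alteration	10	0.450
ARG018	g018	glycopeptide antibiotic	Antibiotic efflux	15	0.650
ARG019	g019	penam	Antibiotic inactivation	18	0.750
ARG020	g020	fluoroquinolone antibiotic	Antibiotic target alteration	27	0.889
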