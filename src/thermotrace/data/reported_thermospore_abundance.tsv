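otu_id	taxon_class	taxon_order	family	PLUS4_R1	PLUS4_R2	PLUS4_R3	MINUS20_R1	MINUS20_R2	MINUS20_R3	MINUS80_R1	MINUS80_R2	MINUS80_R3
Thermospore_1	Unknown	Unknown	Unknown	0	0	0	0	2.7	4.8	17.7	0	12.2
Thermospore_2	Clostridia	Clostridiales	Peptococcaceae	11.6	12.4	12.5	12.7	20.4	21.9	8.7	0	0
Thermospore_3	Clostridia	Clostridiales	Clostridiaceae	4.2	7.4	1.2	3.7	5.5	5.4	9.1	4.9	10.8
Thermospore_4	Clostridia	Clostridiales	Clostridiaceae	4.0	3.6	0	13.3	0	0	0	0	0.5
Thermospore_5	Clostridia	Clostridiales	Clostridiales Incertae Sedis	12.1	11.1	6.7	6.1	0	1.2	0	0	0
Thermospore_6	Bacilli	Bacillales	Bacillaceae	0	0	0	11.0	0	0	0	3.6	0
Thermospore_7	Clostridia	Clostridiales	Unknown	2.6	2.3	4.2	1.7	0	0	0	0	0
Thermospore_8	Clostridia	Clostridiales	Peptococcaceae	0.7	0	0	2.7	0	0	0	8.3	0
Thermospore_9	Clostridia	Unknown	Unknown	0	0	0	1.5	0	0	7.7	0	0
Thermospore_10	Clostridia	Clostridiales	Cluster XI	0.3	0.5	1.1	2.7	2.8	1.6	1.9	5.1	4.5
Thermospore_11	Clostridia	Clostridiales	Unknown	1.5	0	0.6	0	0	0	0	2.2	5.2
Thermospore_12	Clostridia	Unknown	Unknown	2.0	2.2	0.8	1.9	0	0	0	4.0	0
Thermospore_13	Bacilli	Bacillales	Unknown	0.1	0	0.5	0.6	0.7	0.2	0.6	0.8	4.5
Thermospore_14	Clostridia	Clostridiales	Peptococcaceae	0.2	0	0.4	0.5	1.5	0	0	0.3	0
Thermospore_15	Clostridia	Clostridiales	Clostridiaceae	0.2	0.6	0.3	0.1	0.8	0.5	0.6	0.3	0.5
Thermospore_16	Clostridia	Clostridiales	Clostridiaceae	0	0	0	0	0	2.5	0	0	0
Thermospore_17	Bacilli	Bacillales	Bacillaceae	0	0	0	0	0	0	0	0	3.2
Thermospore_18	Clostridia	Clostridiales	Defluviitaleaceae	1.2	0.4	0.7	1.2	1.9	0.9	1.1	1.3	1.4
Thermospore_19	Clostridia	Clostridiales	Clostridiaceae	1.9	2.2	4.9	0.2	3.1	3.4	0	0.5	1.3
Thermospore_20	Clostridia	Clostridiales	Peptostreptococcaceae	0	0	0	0	0	0	0	4.7	0
Thermospore_21	Clostridia	Clostridiales	Clostridiaceae	0.1	0.5	0.7	1.2	0	0	0	0	0.1
Thermospore_22	Clostridia	Clostridiales	Clostridiaceae	0	0	3.0	0	0	0	0	0	0
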