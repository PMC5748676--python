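chrSim	1000	1200	anchor	0	+
chrSim	3176	3274	sno001	0	+
chrSim	4156	4254	sno002	0	+
chrSim	5813	5911	sno003	0	+
chrSim	7242	7340	sno004	0	+
chrSim	8473	8571	sno005	0	+
chrSim	9745	9843	sno006	0	+
chrSim	11297	11395	sno007	0	+
chrSim	12965	13063	sno008	0	+
chrSim	14059	14156	sno009	0	+
chrSim	15694	15792	sno010	0	+
chrSim	17704	17802	sno011	0	+
chrSim	18614	18712	sno012	0	+
chrSim	20566	20664	sno013	0	+
chrSim	22193	22291	sno014	0	+
chrSim	23502	23600	sno015	0	+
chrSim	25282	25382	sno016	0	+
chrSim	26923	27021	sno017	0	+
chrSim	28744	28840	sno018	0	+
chrSim	29737	29835	sno019	0	+
chrSim	30705	30803	sno020	0	+
chrSim	32374	32472	sno021	0	+
chrSim	33636	33734	sno022	0	+
chrSim	34820	34918	sno023	0	+
chrSim	36223	36323	sno024	0	+
chrSim	37993	38091	sno025	0	+
chrSim	39106	39204	sno026	0	+
chrSim	41172	41270	sno027	0	+
chrSim	42575	42673	sno028	0	+
chrSim	43653	43751	sno029	0	+
chrSim	44636	44734	sno030	0	+
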