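id	label
sno001	I
sno002	I
sno003	I
sno004	I
sno005	I
sno006	I
sno007	I
sno008	I
sno009	I
sno010	II
sno011	II
sno012	II
sno013	II
sno014	II
sno015	II
sno016	II
sno017	II
sno018	II
sno019	II
sno020	II
sno021	II
sno022	II
sno023	II
sno024	II
sno025	III
sno026	III
sno027	III
sno028	III
sno029	III
sno030	III
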