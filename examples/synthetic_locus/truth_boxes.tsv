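id	box	start	end	matched	n_mismatches
sno001	C	4	11	ATGATGA	0
sno001	D_prime	35	39	CTGA	0
sno001	C_prime	54	61	GTGATGA	0
sno001	D	90	94	CTGA	0
sno002	C	4	11	ATGATGA	0
sno002	D_prime	35	39	CTGA	0
sno002	C_prime	54	61	GTGATGA	0
sno002	D	90	94	CTGA	0
sno003	C	4	11	ATGATGA	0
sno003	D_prime	35	39	CTGA	0
sno003	C_prime	54	61	GTGATGA	0
sno003	D	90	94	CTGA	0
sno004	C	4	11	ATGATGA	0
sno004	D_prime	35	39	CTGA	0
sno004	C_prime	54	61	GTGATGT	1
sno004	D	90	94	CTGA	0
sno005	C	4	11	ATGATGA	0
sno005	D_prime	35	39	CTGA	0
sno005	C_prime	54	61	GTGATGA	0
sno005	D	90	94	CTGA	0
sno006	C	4	11	ATGATGA	0
sno006	D_prime	35	39	CTGA	0
sno006	C_prime	54	61	GTGATGA	0
sno006	D	90	94	CTGA	0
sno007	C	4	11	ATGATGA	0
sno007	D_prime	35	39	CTGA	0
sno007	C_prime	54	61	GTGATGA	0
sno007	D	90	94	CTGA	0
sno008	C	4	11	ATGATGA	0
sno008	D_prime	35	39	CTGA	0
sno008	C_prime	54	61	GTGATGA	0
sno008	D	90	94	CTGA	0
sno009	C	4	11	ATGATGA	0
sno009	D_prime	35	39	CTGA	0
sno009	C_prime	53	60	GTGATGA	0
sno009	D	89	93	CTGA	0
sno010	C	4	11	ATGATGA	0
sno010	D_prime	35	39	CTGA	0
sno010	C_prime	54	61	GTGATGA	0
sno010	D	90	94	CTGA	0
sno011	C	4	11	ATGATGA	0
sno011	D_prime	35	39	CTGA	0
sno011	C_prime	54	61	GTGATGA	0
sno011	D	90	94	CTGA	0
sno012	C	4	11	ATGATGA	0
sno012	D_prime	35	39	CTGA	0
sno012	C_prime	54	61	GTGATGA	0
sno012	D	90	94	CTGA	0
sno013	C	4	11	ATGATGA	0
sno013	D_prime	35	39	CTGA	0
sno013	C_prime	54	61	GTGATGA	0
sno013	D	90	94	CTGA	0
sno014	C	4	11	ATGATGA	0
sno014	D_prime	35	39	CTGA	0
sno014	C_prime	54	61	GTGATGA	0
sno014	D	90	94	CTGA	0
sno015	C	4	11	ATGATGA	0
sno015	D_prime	35	39	CCGA	1
sno015	C_prime	54	61	GTGATGA	0
sno015	D	90	94	CTGA	0
sno016	C	4	11	ATGATGA	0
sno016	D_prime	35	39	CTGA	0
sno016	C_prime	54	61	GTGATGA	0
sno016	D	92	96	CTGA	0
sno017	C	4	11	ATGCTGA	1
sno017	D_prime	35	39	CTGA	0
sno017	C_prime	54	61	GTGATGA	0
sno017	D	90	94	CTGA	0
sno018	C	4	11	ATGATGA	0
sno018	D_prime	35	39	CTGA	0
sno018	C_prime	54	61	GTGATGA	0
sno018	D	88	92	CTGA	0
sno019	C	4	11	ATGATGA	0
sno019	D_prime	35	39	CTGA	0
sno019	C_prime	54	61	GTGATGA	0
sno019	D	90	94	CTGA	0
sno020	C	4	11	ATGATGA	0
sno020	D_prime	35	39	CTGA	0
sno020	C_prime	54	61	GTGATGA	0
sno020	D	90	94	CTGA	0
sno021	C	4	11	ATAATGA	1
sno021	D_prime	35	39	CTGA	0
sno021	C_prime	54	61	GTGATGA	0
sno021	D	90	94	CTGA	0
sno022	C	4	11	ATGATGA	0
sno022	D_prime	35	39	CTGA	0
sno022	C_prime	54	61	GTGATGA	0
sno022	D	90	94	CTGA	0
sno023	C	4	11	ATGATGA	0
sno023	D_prime	35	39	CTTA	1
sno023	C_prime	54	61	GCGATGA	1
sno023	D	90	94	CTGA	0
sno024	C	4	11	ATGATGA	0
sno024	D_prime	35	39	CTGA	0
sno024	C_prime	54	61	GTGATGA	0
sno024	D	92	96	CTGA	0
sno025	C	4	11	ATGATGA	0
sno025	D_prime	35	39	CTGA	0
sno025	C_prime	54	61	GTGATGA	0
sno025	D	90	94	CTGA	0
sno026	C	4	11	ATGATGA	0
sno026	D_prime	35	39	CTGA	0
sno026	C_prime	54	61	GTGATGA	0
sno026	D	90	94	CTGA	0
sno027	C	4	11	ATGATGA	0
sno027	D_prime	35	39	CTGA	0
sno027	C_prime	54	61	GTGATGA	0
sno027	D	90	94	CTGA	0
sno028	C	4	11	ATGATGA	0
sno028	D_prime	35	39	GTGA	1
sno028	C_prime	54	61	GTGATGA	0
sno028	D	90	94	CTGA	0
sno029	C	4	11	ATGATGA	0
sno029	D_prime	35	39	CTGA	0
sno029	C_prime	54	61	GTGATGA	0
sno029	D	90	94	CTGA	0
sno030	C	4	11	AAGATGA	1
sno030	D_prime	36	40	CTGA	0
sno030	C_prime	54	61	GTGATGA	0
sno030	D	90	94	CTGA	0
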