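marker	section	p1_chrom	p1_start	p1_end	p2_chrom	p2_start	p2_end	hit_chrom	hit_start	hit_end	willow_lg
XI_19_sa	paralog2	XI	13708412	13713847	I	34332298	34337706	I	34336820	34337014	Ib
VI_21_sa	paralog2	VI	1059584	1063805	XVI	175981	180636	XVI	179650	180165	Ib
XI_14om_sa	paralog2	XI	13390381	13396292	XIII	8162057	8167721	XIII	8162846	8163488	Ib
XVII_8om_sa	paralog2	XVII	2862545	2865794	I	21917969	21921284	I	21918035	21918509	Ib
V-3	paralog2	V			NA			II	7149915	7150175	II
XIV_2om_sa_pI+pIII	paralog2	XIV	1405173	1410344	II	11032656	11037852	II	11034560	11035232	II
I-3_sa	paralog2	I	2799329	2802489	III	16679089	16681782	III	16679770	16679455	III
II_27_sa	paralog2	II	659865	663083	V	17347198	17350454	V	17347673	17348033	V
X_23_sa_pI	paralog2	X	2909535	2910774	VIII	13507022	13508215	VIII	13507309	13508014	VIII
X_5_sa_pI+pIII	paralog2	X	4387251	4392821	scaff.132	44316	50181	scaff.132	46692	47354	VIII
I_55_sa	paralog2	I	19888722	19894389	IX	6182711	6188752	IX	6188219	6188751	IX
I_56_sa	paralog2	I	20786788	20790053	IX	5366669	5370261	IX	5368352	5368805	IX
R_79_sa	paralog2	VIII	2675046	2678768	X	18365204	18369371	X	18368575	18368938	X
I-64_sa	paralog2	I	28954163	28960895	XI	5889680	5902742	XI	5899792	5899792	XI
XV_14_sa	paralog2	XV	4861609	4865109	XII	9029417	9031788	XII	9030854	9031468	XII
XV_3om_sa	paralog2	XV	2214022	2229691	XII	5650497	5668349	XII	5659107	5659662	XII
XIX_16_sa	paralog2	XIX	10024624	10029438	scaff.142	594094	598587	scaff.142	595203	595639	XIII
II-22_sa	paralog2	II	20278259	20280545	XIV	7371540	7374037	XIV	7372638	7372921	XIV
II-15_sa	paralog2	II	13716352	13719221	XIV	3952304	3955719	XIV	3952744	3952880	XIV
R-76_sa	paralog2	XIII	13007808	13016472	XIX	10828344	10837472	XIX	10828231	10828870	XIX
I-44_sa	other	I	8108096	8110817	III	11697654	11701038	I	28482702	28483096	Ib
VI_20_sa	other	VI	175694	177367	I	24601135	24605961	scaff.137	193270	193790	Ib
XVI-4_sa	other	XVI	3509806	3516550	VI	3514697	3520404	XVI	3668954	3669420	Ib
VI-22_sa	other	VI	9566935	9572156	scaff.215	114354	120054	IV	16209337	16209466	B
XI-5	translocation	XI			NA			XI	14789231	14789785	Ib
XIII-9_sa	translocation	XIII	8154297	8159215	NA			XIII	8156663	8157295	Ib
XIV_20_sa	translocation	XIV	13995907	14001590	NA			XIV	13996955	13997593	II
XVIII_3_sa	translocation	XVIII	2310344	2313479	NA			XVIII	2312570	2312814	VI
III_23_sa_pI+pIII	translocation	III	8892578	8897817	NA			III	8892660	8893230	VII
II_37_sa_pI	translocation	II	20797060	20804409	IV	7209830	7217966	II	20803016	20803505	XVII
II-23_sa	translocation	II	21561743	21565690	NA			II	21562039	21562808	XVII
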