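logFC	logCPM	PValue	FDR
G01	0.335461230010464	15.4032149748333	0.354220556309169	0.923127226220826
G02	-0.270257911632251	14.8187107161673	0.476044684908771	0.954469865019876
G03	-0.736197506439417	15.0593129553105	0.0475621674494479	0.475621674494479
G04	-0.451668518918563	15.1085265003503	0.223500116694063	0.7716930700901
G05	-0.151916645372518	15.3577183763806	0.678071904838856	0.982933247395094
G06	-0.0905931399649078	14.9792609105883	0.826814956911056	0.992177948293268
G07	0.203963663324711	15.0432512705882	0.598712860734105	0.982933247395094
G08	-0.134900805707095	15.3421658120584	0.726377766529574	0.982933247395094
G09	0.338561084815851	14.9137213311237	0.36925089048833	0.923127226220826
G10	-1.13770340596789	15.1158938905446	0.00224516893541852	0.0673550680625556
G11	0.270069903731298	15.0045830478385	0.477234932509938	0.954469865019876
G12	-0.348959915380579	15.0691362838424	0.339196491817909	0.923127226220826
G13	-0.599717530858744	14.5749864094859	0.114025299226295	0.570126496131477
G14	-0.0224826301055821	15.039234790405	0.966377321709207	0.999700677630214
G15	-0.0051830380545053	15.2249785736844	1	1
G16	-0.0453920296293269	14.8609203973601	0.905289268374863	0.999143123486488
G17	0.138306408044677	14.8713845058445	0.722665242529214	0.982933247395094
G18	-0.223370666182233	14.9784066637305	0.553252867490245	0.982933247395094
G19	0.778167871661852	15.0404519098829	0.0385078985671589	0.475621674494479
G20	-0.455069974429579	15.0490250926016	0.223429471407806	0.7716930700901
G21	0.110818140137429	14.7518372639604	0.776559934257363	0.982933247395094
G22	0.30415311411322	15.1475625391961	0.405023118337771	0.934668734625626
G23	0.584533376025287	15.394535212686	0.106211743382249	0.570126496131477
G24	-0.172743117379511	15.2002547574731	0.645586095413741	0.982933247395094
G25	0.106844274264929	15.0565157292995	0.786346597916075	0.982933247395094
G26	0.0356659929218886	15.0191351864279	0.931905197260681	0.999143123486488
G27	-0.0412239042377015	15.0282629107356	0.932533581920722	0.999143123486488
G28	0.195646720613355	15.2979465613074	0.602387036839306	0.982933247395094
G29	0.594581413818276	15.3334345788754	0.0957812148792374	0.570126496131477
G30	0.458943757671551	14.9142171345205	0.23150792102703	0.7716930700901
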