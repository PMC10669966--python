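logFC	logCPM	PValue	FDR
G01	0.335459453960262	15.4029835069768	0.350443871404854	0.899524146380751
G02	-0.270408411342272	14.8161605617435	0.469920416406622	0.939840832813245
G03	-0.736155883975284	15.0592120049868	0.0433342472440158	0.433342472440158
G04	-0.451757324773652	15.1074701897664	0.215971768323719	0.741171632128203
G05	-0.151951331381759	15.3584611065413	0.67550988038587	0.977705126573423
G06	-0.0902687435106007	14.9792454468426	0.822716273777453	0.987259528532944
G07	0.203801436263322	15.0450521589876	0.591064939744457	0.977705126573423
G08	-0.134997577519311	15.3427152518916	0.724113673562778	0.977705126573423
G09	0.338570731002434	14.9135731247341	0.3598096585523	0.899524146380751
G10	-1.13774464223626	15.1152873783834	0.00190937238502748	0.0572811715508245
G11	0.269899965649095	15.0066996818007	0.466890582251723	0.939840832813245
G12	-0.348745679610005	15.069726300784	0.330011926087331	0.899524146380751
G13	-0.599714125828288	14.572469398332	0.113351240011486	0.56675620005743
G14	-0.022393457700633	15.0415550574036	0.965662798214858	0.998961515394681
G15	-0.00514967971429636	15.2239163308783	1	1
G16	-0.0453056726814368	14.8612985842216	0.903726039178416	0.997554874068093
G17	0.138175583646459	14.8714651843561	0.718087712286973	0.977705126573423
G18	-0.223165068414785	14.9785496950941	0.559835611013363	0.977705126573423
G19	0.778487453547691	15.0420147131347	0.0345992913272131	0.433342472440158
G20	-0.455065374953268	15.0453758983828	0.21405264848292	0.741171632128203
G21	0.110702489264245	14.7523281067169	0.774342472139475	0.977705126573423
G22	0.304166083296088	15.1479707806128	0.398591830582448	0.919827301344111
G23	0.584547896650037	15.395395088486	0.103454655681769	0.56675620005743
G24	-0.172692209025348	15.1998391380553	0.642182218599818	0.977705126573423
G25	0.106800289353397	15.0557638187709	0.782164101258738	0.977705126573423
G26	0.0355243714055075	15.0189320532946	0.930367749879502	0.997554874068093
G27	-0.0413682761812921	15.0254248188137	0.931051215796887	0.997554874068093
G28	0.195680178056661	15.2982618706815	0.599065874694905	0.977705126573423
G29	0.594485187227237	15.3346476965751	0.0929246522311811	0.56675620005743
G30	0.459182720768384	14.9145811763372	0.222351489638461	0.741171632128203
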