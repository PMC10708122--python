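id	peptide_a	peptide_b	cm	z_list	mz_calc_list	mz_obs_list	rt_list	isotope_error_flag
1	AGYLEKR	RIYQFTAASPK	24	4	536.043	536.0420	40.2	0
2	ALEEAMEQK	ALEEAMEQKAELER	12	4	677.3295	677.3230	53.7	0
3	ALSTDPAAPNLKSQLAAAAR	LNEAAAGLNQAATELVQASRGTPQDLAR	24	5	971.715	971.715	102.9	0
4	ANLEKAK	KEEELQAALARVEEEAAQK	24	4 5	735.3925 588.5154	735.3925 588.5156	66.9 67.0	0
5	AQYEDIAQK	SKAEAESLYQSK	12	4	605.0512	605.0511	32	0
6	ATKEQLK	FQNALLVRYTK	24	4 5	549.0652 439.4536	549.0655 439.4538	43.0 43.1	0
7	AVFPSIVGRPR	GILTLKYPIEHGIITNWDDMEK	24	4 5 6	952.7618 762.4109 635.5103	952.7612 762.4112 635.5105	99.1 99.5 99.0	0
8	AVFPSIVGRPR	RGILTLKYPIEHGIITNWDDMEK	24	6	661.5272	661.5275	92.8	0
9	AVPAEGVR	LLLPGELAKHAVSEGTK	24	4	646.8669	646.8665	91.9	0
10	DAMVARAR	LGGSQEDQIKNAIDK	24	4	632.8276	632.8277	50.7	0
11	DAQIFIQKK	NFTEVHPDYGSHIQALLDK	12	4 5	822.178 657.9439	822.1781 657.9442	73.1 73.1	0
12	DAVTYTEHAKR	RSTITSREIQTAVR	24	5	587.1137	587.1135	31.7	0
13	DAVTYTEHAKR	STITSREIQTAVR	24	4 5	694.6151 555.8935	694.6149 555.8934	36.8 36.9	0
14	DLKDFIR	IGQLSEKEIQK	12	5	438.8484	439.2515	42.8	0
15	EEALNNAFK	ALEEAMEQKAELER	24	4	677.0826	677.33375	53.9	1
16	EKGRDLAPR	EKGRDLAPR	24	4	527.2936	527.2959	75.9	0
17	EKYISLR	IGQLSEKEIQK	12	5	439.2515	439.4538	43.1	1
18	ELSGPEGK	FQNALLVRYTK	24	4	548.7982	548.7982	43	0
19	FGERAFK	LAKTYETTLEK	24	4	544.2928	544.293	40.8	0
20	FKDCHLAR	CSTSPLLEACEFLRK	24	5 6	576.8849 480.9053	576.8852 480.9054	67.4 67.3	0
21	FKDCHLAR	HFENKFAVETLICS	24	5	553.6725	553.6729	65.6	0
22	FQNALLVRYTK	KVPQVSTPTLVEVSR	24	4 5	754.6802 603.9456	754.6804 603.9458	73.7 73.8	0
23	IAGEASRLAHYNK	NSLLTDIIAAYQR	12	4	730.3925	730.3901	71	0
24	IAGEASRLAHYNK	TVTAMDVVYALKR	24	4 5 6	730.6432 584.716 487.4312	730.6436 584.7161 487.4313	72.1 72.0 72.0	0
25	IAGEASR	TVTAMDVVYALKR	24	4	549.0479	549.0475	79.2	0
26	IASAEGR	TLGASGRYEGKIAR	12	4	549.0488	549.0477	79.4	0
27	KESYSVYVYK	TVTAMDVVYALK	12	4	647.5896	647.5913	74.9	0
28	KPAPKTPPK	KVPQVSTPTLVEVSR	24	4	657.3877	657.3879	61.8	0
29	KSHEESHKE	LLETECPQYIR	12	4	636.5603	636.5604	17.8	0
30	KSHEESHKE	LLETECPQYIRK	24	4 5 6	671.5841 537.4687 448.0585	671.5840 537.4684 448.0583	15.2 15.9 16.1	0
31	LKCASLQK	IAQDKLNDIK	24	4	532.8003	532.8015	39.7	0
32	LKQVLLHQQAK	NLLFNDNTECLAR	24	4	727.892	727.8919	65.2	0
33	MADMQNLVER	LLETECPQYIRK	12	4	692.5948	692.5941	58.8	0
34	MGVAAHKK	LLETECPQYIRK	24	4	604.3225	604.3228	28.7	0
35	NLAEKAK	KEEELQAALARVEEEAAQK	24	4	735.3925	735.3928	67	0
36	NLLFNDNTECLAR	CLAENAGDVAFVKDVTVLQNTDGNNNEAWAK	12	5	991.6732	991.6738	100.1	0
37	NLVNNLRK	LIELAKDMPSLK	24	5	471.0754	471.0758	68.5	0
38	RSTITSR	DAVTYTEHAKR	24	4	534.2804	534.2802	17.5	0
39	SHEESHKE	LLETECPQYIR	12	4	604.5366	604.5362	22.3	0
40	SHEESHKE	LLETECPQYIRK	24	5	511.8497	511.8496	23.2	0
41	SILENLRSK	YLQEIYNSNNQKIVNLK	24	4	791.6832	791.6837	73.1	0
42	SLAGMLTPYVAR	IAGEASRLAHYNK	12	4	680.6142	680.6152	61.4	0
43	VAQQEIK	FQNALLVRYTK	24	5	439.0505	439.2513	42.9	1
44	VPQSGTLK	EQIQVPSNLALK	24	4	548.8126	549.0652	43.1	1
45	VVAGVANALAHK	VLGAFSDGLAHLDNLKGTFATLSELHCDK	12	6	715.8784	715.8791	101.9	0
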