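gene_id	S_early/S0	S_late/S0	R_early/R0	R_late/R0	description	go_bp	go_cc
LOC_Os03g44880	-3.0699	-7.6904	6.2795	4.4616	Putative germin-like protein 3-2	response to stress	extracellular region
LOC_Os08g35760	-2.9850	-6.8739	5.0342	4.1843	Germin-like protein 8-14	divalent metal ion transport	extracellular region
LOC_Os02g44320	-2.6067	-5.5841	3.5159	2.1718	14 kDa proline-rich protein DC2.15	lipid transport	extracellular region
LOC_Os10g40420	-1.7318	-3.7710	3.7780	2.4650	Plant lipid transfer protein	lipid transport	extracellular region
LOC_Os07g18750	-1.5582	-3.2059	3.0342	1.9405	Plant lipid transfer protein DIR1	lipid transport	extracellular region
LOC_Os05g10330	-1.1491	-3.4066	2.5768	1.2144	Similar to Stem 28 kDa glycoprotein	metabolic process	extracellular region
LOC_Os03g04530	-1.7801	-4.5678	3.1341	1.7710	Cytochrome P450 family protein	oxidation-reduction process	extracellular region
LOC_Os06g28000	-2.2380	-3.8361	2.6389	1.3979	Protein of unknown function DUF239		extracellular region
LOC_Os01g21034	-2.0392	-4.2691	3.2111	1.4877	Pectinesterase	cell wall organization	cell wall
LOC_Os11g03160	-1.0261	-2.5074	2.3742	1.2931	Glycosyl transferase, family 8 protein	cell wall organization	membrane
LOC_Os05g34320	-1.4953	-4.2403	3.1718	1.6017	Glycoside hydrolase	carbohydrate metabolic	cell wall
LOC_Os01g47780	-1.3583	-3.5887	3.3331	1.6020	Fasciclin-like arabinogalactan protein 11	plant-type secondary cell wall biogenesis	anchored component of membrane
LOC_Os08g34320	-1.5146	-4.1849	3.6937	2.0720	Protein of unknown function DUF566
LOC_Os05g38000	-1.0291	-3.5098	2.9374	1.8637	Rop guanine nucleotide exchange factor 7	positive regulation of Rho GTPase activity	plasma membrane
LOC_Os07g29780	-1.1778	-3.9431	2.6677	1.1438	Rop guanine nucleotide exchange factor 3	positive regulation of Rho GTPase activity	plasma membrane
LOC_Os09g17660	-1.8677	-4.6194	3.5913	1.9719	HSP20-like chaperone protein	response to stress	cell
LOC_Os01g55560	-1.0358	-3.1142	3.8714	2.1315	Probable protein ABIL5	anatomical structure morphogenesis	SCAR complex
LOC_Os08g14700	-1.9333	-2.4197	2.4781	1.5860	Glucan endo-1,3-beta-glucosidase 7	regulation of meristem growth	cell
LOC_Os07g37850	-1.5484	-5.5175	3.4314	1.2854	Similar to LLA-115		cell
LOC_Os01g05840	-1.1587	-4.1744	3.0301	1.1690	Short-chain dehydrogenase TIC 32	oxidation-reduction process
LOC_Os08g33660	-1.4375	-3.6294	3.4132	1.9560	Transcription factor MYB106	anatomical structure morphogenesis	nucleus
LOC_Os07g01530	-1.2440	-3.3855	2.5365	1.0732	NB-ARC domain containing protein	defense response	nucleus
LOC_Os02g45420	-1.2912	-1.7180	1.7674	1.3400	Ethylene response factors	response to stress	nucleus
LOC_Os01g72270	1.5876	3.9238	-2.0629	-1.4023	Cytochrome P450, family 94, CYP94D	oxidation-reduction process
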