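gene	omim_id	disease	inheritance	hpo_terms	onset	sf_list	gene_status	lof_mechanism	paralog_support	literature_hpo
NFIA	600727	Brain malformations with or without urinary tract defects	AD	HP:0001274|HP:0002119|HP:0002079	prenatal	0	established	1	0	
ARV1	611647	Epileptic encephalopathy, early infantile, 38	AR	HP:9000103|HP:0000238	prenatal	0	established	1	0	
ATRX	300032	Alpha-thalassemia/mental retardation syndrome	XLR	HP:0002079|HP:0000238	prenatal	0	established	1	0	
KCNK9	605874	Birk-Barel syndrome	AD	HP:0000347|HP:0000175	prenatal	0	established	1	0	
FREM2	617524	Fraser syndrome 2	AR	HP:9000110|HP:0000316	prenatal	0	established	1	0	
CRYAA	123580	Cataract 9, multiple types	AD	HP:9000112	prenatal	0	established	0	0	
ZFPM2	603693	Diaphragmatic hernia 3	AD	HP:0000776	prenatal	0	established	1	0	
LRP2	600073	Donnai-Barrow syndrome	AR	HP:0000776|HP:0002202	prenatal	0	established	1	0	
MAPK1	176948	Noonan syndrome 13	AD	HP:0001636|HP:0001629|HP:9000130	prenatal	0	established	1	0	
LZTR1	600574	Noonan syndrome 2	AR	HP:0001629|HP:0001640	prenatal	0	established	1	0	
FLNA	300017	Periventricular nodular heterotopia / cardiac valvular dysplasia	XLD	HP:0001629|HP:0001640	prenatal	0	established	0	0	
CDKN1C	600856	Beckwith-Wiedemann syndrome	AD	HP:0001539	prenatal	0	established	1	0	
TMEM67	609884	Meckel syndrome 3	AR	HP:9000140|HP:0001541	prenatal	0	established	1	0	
HNF1B	189907	Renal cysts and diabetes syndrome	AD	HP:0000107|HP:9000151	prenatal	0	established	1	0	
PKHD1	606702	Polycystic kidney disease 4	AR	HP:0000126|HP:9000151	prenatal	0	established	1	0	
CLCN5	300008	Dent disease 1	XLR	HP:0000107	prenatal	0	established	1	0	HP:9000200|HP:0001561
GDF5	601146	Multiple synostoses syndrome 2	AD	HP:9000160|HP:0001155	prenatal	0	established	1	0	
TPM2	190990	Arthrogryposis, distal, type 1A	AD	HP:0001762|HP:9000164	prenatal	0	established	0	0	
PLOD3	603066	Bone fragility with contractures, arterial rupture, and deafness	AR	HP:0001155|HP:9000105	prenatal	0	established	1	0	
ZC4H2	300897	Wieacker-Wolff syndrome	XLD	HP:0001762|HP:0001155	prenatal	0	established	1	0	
UBA1	314370	Spinal muscular atrophy, X-linked 2	XLR	HP:0000347|HP:9000163	prenatal	0	established	0	0	
RASA1	139150	Capillary malformation with hydrops	AD	HP:9000170	prenatal	0	established	1	0	
PIEZO1	611184	Lymphatic dysplasia with hydrops fetalis	AR	HP:9000170|HP:0001541	prenatal	0	established	1	0	
KAT6A	601408	Arboleda-Tham syndrome	AD	HP:0001511	prenatal	0	established	1	0	
PLK4	605031	Microcephaly and chorioretinopathy with growth retardation	AR	HP:9000180	prenatal	0	established	1	0	
PTPN11	176876	Noonan syndrome 1	AD	HP:0010880|HP:9000190	prenatal	0	established	1	0	
NEB	161650	Nemaline myopathy with fetal akinesia	AR	HP:9000190|HP:0010880	prenatal	0	established	1	0	
SCN1A	182389	Dravet syndrome	AD	HP:0001250	childhood	0	established	1	0	
KCNQ2	602235	Developmental and epileptic encephalopathy 7	AD	HP:0001250|HP:0001249	childhood	0	established	1	0	
GJB2	121011	Deafness, autosomal recessive 1A	AR	HP:0000407	childhood	0	established	1	0	
PAH	612349	Phenylketonuria	AR	HP:9000210|HP:0001249	childhood	0	established	1	0	
RB1	614041	Retinoblastoma	AD	HP:9000220	childhood	1	established	1	0	
BRCA2	600185	Breast-ovarian cancer, familial, 2	AD	HP:9000221	adult	1	established	1	0	
LDLR	606945	Familial hypercholesterolemia	AD	HP:9000211	adult	1	established	1	0	
SMARCC2		candidate: chromatin remodelling paralog			childhood	0	undefined	0	1	
CAMK2D		candidate: cardiac kinase, animal-model support			childhood	0	undefined	0	1	
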