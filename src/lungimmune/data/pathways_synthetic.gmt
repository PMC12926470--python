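B_cell_receptor_signaling	synthetic	Cd19	Cd79a	Cd79b	Ms4a1	Pax5	Ebf1	Ighm	Iglc1
T_cell_receptor_signaling	synthetic	Cd3e	Cd3d	Cd3g	Trac	Trbc1	Lat	Lck	Cd28
NK_cell_mediated_cytotoxicity	synthetic	Ncr1	Gzma	Gzmb	Prf1	Klrk1	Klrc1	Nkg7	Fcgr3
Phagosome	synthetic	Csf1r	Lyz2	Fcgr1	Mertk	Cd68	Itgam	Vsig4	Cd74
MAPK_signaling	synthetic	Jun	Fos	Ier2	Ier5	Dusp2	Klf6	Nr4a1	Pim1
NFkB_signaling	synthetic	Ubb	Ubc	Btg2	Tnfsf10	Cd40	Cd69	S100a11
Cytokine_receptor_interaction	synthetic	Ccl5	Ccr5	Ccr2	Ccr6	Ccr7	Cxcr3	Xcl1	Xcr1	Il7r	Il2ra	Il17a	Il17ra	Ifngr1
Antigen_processing_presentation	synthetic	H2-Ab1	H2-Aa	H2-Q7	Cd74	Ciita	Psme2b	Tapbp
TGF_beta_signaling	synthetic	Tgfb1	Tgfbr1	Tgfbr2	Fau	Serf2
Oxidative_phosphorylation	synthetic	Cox7c	Cox4i1	Ndufb1	Atp5md	Uba52	Ldha
Glycolysis	synthetic	Ldha	Slc2a1	Hk2	Eno3	Eno1	Pkm
Heat_shock_response	synthetic	Hspa1a	Hspa1b	Hspa8	Hsp90ab1	Dnajb1
Cell_adhesion_molecules	synthetic	Itga2	Itgb2	Sell	Selplg	Spn	Emb	Cd6
Th17_differentiation	synthetic	Rorc	Il17a	Il17f	Ccr6	Stat3
Treg_program	synthetic	Foxp3	Il2ra	Ctla4	Ikzf2	Tnfrsf18
Plasma_cell_differentiation	synthetic	Jchain	Xbp1	Prdm1	Sdc1	Irf4
B_cell_development	synthetic	Vpreb1	Igll1	Dntt	Rag1	Rag2	Kit	Flt3	Sox4
Chemotaxis	synthetic	Ccl5	Xcl1	Ccr2	Ccr5	Ccr6	Ccr7	Cxcr3	S100a10
Interferon_response	synthetic	Ifng	Ifngr1	Ifi27l2a	Ly6c2	Ly6a
Apoptosis	synthetic	Bcl2	Mcl1	Pdcd1	Stk17b	Pdcd4
Random_set_A	synthetic	Gene00001	Gene00002	Gene00003	Gene00004	Gene00005	Gene00006
Random_set_B	synthetic	Gene00010	Gene00011	Gene00012	Gene00013	Gene00014
Random_set_C	synthetic	Gene00020	Gene00021	Gene00022	Gene00023	Gene00024	Gene00025	Gene00026
Random_set_D	synthetic	Gene00030	Gene00031	Gene00032	Gene00033
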