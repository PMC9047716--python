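label,name,hemisphere,group
4,Left-Lateral-Ventricle,L,subcortical
5,Left-Inf-Lat-Vent,L,subcortical
7,Left-Cerebellum-White-Matter,L,subcortical
8,Left-Cerebellum-Cortex,L,subcortical
10,Left-Thalamus-Proper,L,subcortical
11,Left-Caudate,L,subcortical
12,Left-Putamen,L,subcortical
13,Left-Pallidum,L,subcortical
14,3rd-Ventricle,B,subcortical
15,4th-Ventricle,B,subcortical
16,Brain-Stem,B,subcortical
17,Left-Hippocampus,L,subcortical
18,Left-Amygdala,L,subcortical
19,Left-Insula,L,subcortical
24,CSF,B,subcortical
26,Left-Accumbens-area,L,subcortical
28,Left-VentralDC,L,subcortical
30,Left-vessel,L,subcortical
31,Left-choroid-plexus,L,subcortical
43,Right-Lateral-Ventricle,R,subcortical
44,Right-Inf-Lat-Vent,R,subcortical
46,Right-Cerebellum-White-Matter,R,subcortical
47,Right-Cerebellum-Cortex,R,subcortical
49,Right-Thalamus-Proper,R,subcortical
50,Right-Caudate,R,subcortical
51,Right-Putamen,R,subcortical
52,Right-Pallidum,R,subcortical
53,Right-Hippocampus,R,subcortical
54,Right-Amygdala,R,subcortical
55,Right-Insula,R,subcortical
58,Right-Accumbens-area,R,subcortical
60,Right-VentralDC,R,subcortical
62,Right-vessel,R,subcortical
63,Right-choroid-plexus,R,subcortical
72,5th-Ventricle,B,subcortical
77,WM-hypointensities,B,subcortical
80,non-WM-hypointensities,B,subcortical
85,Optic-Chiasm,B,subcortical
251,CC_Posterior,B,subcortical
252,CC_Mid_Posterior,B,subcortical
253,CC_Central,B,subcortical
254,CC_Mid_Anterior,B,subcortical
255,CC_Anterior,B,subcortical
11101,ctx_lh_G_and_S_frontomargin,L,cortical
11102,ctx_lh_G_and_S_occipital_inf,L,cortical
11103,ctx_lh_G_and_S_paracentral,L,cortical
11104,ctx_lh_G_and_S_subcentral,L,cortical
11105,ctx_lh_G_and_S_transv_frontopol,L,cortical
11106,ctx_lh_G_and_S_cingul-Ant,L,cortical
11107,ctx_lh_G_and_S_cingul-Mid-Ant,L,cortical
11108,ctx_lh_G_and_S_cingul-Mid-Post,L,cortical
11109,ctx_lh_G_cingul-Post-dorsal,L,cortical
11110,ctx_lh_G_cingul-Post-ventral,L,cortical
11111,ctx_lh_G_cuneus,L,cortical
11112,ctx_lh_G_front_inf-Opercular,L,cortical
11113,ctx_lh_G_front_inf-Orbital,L,cortical
11114,ctx_lh_G_front_inf-Triangul,L,cortical
11115,ctx_lh_G_front_middle,L,cortical
11116,ctx_lh_G_front_sup,L,cortical
11117,ctx_lh_G_Ins_lg_and_S_cent_ins,L,cortical
11118,ctx_lh_G_insular_short,L,cortical
11119,ctx_lh_G_occipital_middle,L,cortical
11120,ctx_lh_G_occipital_sup,L,cortical
11121,ctx_lh_G_oc-temp_lat-fusifor,L,cortical
11122,ctx_lh_G_oc-temp_med-Lingual,L,cortical
11123,ctx_lh_G_oc-temp_med-Parahip,L,cortical
11124,ctx_lh_G_orbital,L,cortical
11125,ctx_lh_G_pariet_inf-Angular,L,cortical
11126,ctx_lh_G_pariet_inf-Supramar,L,cortical
11127,ctx_lh_G_parietal_sup,L,cortical
11128,ctx_lh_G_postcentral,L,cortical
11129,ctx_lh_G_precentral,L,cortical
11130,ctx_lh_G_precuneus,L,cortical
11131,ctx_lh_G_rectus,L,cortical
11132,ctx_lh_G_subcallosal,L,cortical
11133,ctx_lh_G_temp_sup-G_T_transv,L,cortical
11134,ctx_lh_G_temp_sup-Lateral,L,cortical
11135,ctx_lh_G_temp_sup-Plan_polar,L,cortical
11136,ctx_lh_G_temp_sup-Plan_tempo,L,cortical
11137,ctx_lh_G_temporal_inf,L,cortical
11138,ctx_lh_G_temporal_middle,L,cortical
11139,ctx_lh_Lat_Fis-ant-Horizont,L,cortical
11140,ctx_lh_Lat_Fis-ant-Vertical,L,cortical
11141,ctx_lh_Lat_Fis-post,L,cortical
11142,ctx_lh_Pole_occipital,L,cortical
11143,ctx_lh_Pole_temporal,L,cortical
11144,ctx_lh_S_calcarine,L,cortical
11145,ctx_lh_S_central,L,cortical
11146,ctx_lh_S_cingul-Marginalis,L,cortical
11147,ctx_lh_S_circular_insula_ant,L,cortical
11148,ctx_lh_S_circular_insula_inf,L,cortical
11149,ctx_lh_S_circular_insula_sup,L,cortical
11150,ctx_lh_S_collat_transv_ant,L,cortical
11151,ctx_lh_S_collat_transv_post,L,cortical
11152,ctx_lh_S_front_inf,L,cortical
11153,ctx_lh_S_front_middle,L,cortical
11154,ctx_lh_S_front_sup,L,cortical
11155,ctx_lh_S_interm_prim-Jensen,L,cortical
11156,ctx_lh_S_intrapariet_and_P_trans,L,cortical
11157,ctx_lh_S_oc_middle_and_Lunatus,L,cortical
11158,ctx_lh_S_oc_sup_and_transversal,L,cortical
11159,ctx_lh_S_occipital_ant,L,cortical
11160,ctx_lh_S_oc-temp_lat,L,cortical
11161,ctx_lh_S_oc-temp_med_and_Lingual,L,cortical
11162,ctx_lh_S_orbital_lateral,L,cortical
11163,ctx_lh_S_orbital_med-olfact,L,cortical
11164,ctx_lh_S_orbital-H_Shaped,L,cortical
11165,ctx_lh_S_parieto_occipital,L,cortical
11166,ctx_lh_S_pericallosal,L,cortical
11167,ctx_lh_S_postcentral,L,cortical
11168,ctx_lh_S_precentral-inf-part,L,cortical
11169,ctx_lh_S_precentral-sup-part,L,cortical
11170,ctx_lh_S_suborbital,L,cortical
11171,ctx_lh_S_subparietal,L,cortical
11172,ctx_lh_S_temporal_inf,L,cortical
11173,ctx_lh_S_temporal_sup,L,cortical
11174,ctx_lh_S_temporal_transverse,L,cortical
12101,ctx_rh_G_and_S_frontomargin,R,cortical
12102,ctx_rh_G_and_S_occipital_inf,R,cortical
12103,ctx_rh_G_and_S_paracentral,R,cortical
12104,ctx_rh_G_and_S_subcentral,R,cortical
12105,ctx_rh_G_and_S_transv_frontopol,R,cortical
12106,ctx_rh_G_and_S_cingul-Ant,R,cortical
12107,ctx_rh_G_and_S_cingul-Mid-Ant,R,cortical
12108,ctx_rh_G_and_S_cingul-Mid-Post,R,cortical
12109,ctx_rh_G_cingul-Post-dorsal,R,cortical
12110,ctx_rh_G_cingul-Post-ventral,R,cortical
12111,ctx_rh_G_cuneus,R,cortical
12112,ctx_rh_G_front_inf-Opercular,R,cortical
12113,ctx_rh_G_front_inf-Orbital,R,cortical
12114,ctx_rh_G_front_inf-Triangul,R,cortical
12115,ctx_rh_G_front_middle,R,cortical
12116,ctx_rh_G_front_sup,R,cortical
12117,ctx_rh_G_Ins_lg_and_S_cent_ins,R,cortical
12118,ctx_rh_G_insular_short,R,cortical
12119,ctx_rh_G_occipital_middle,R,cortical
12120,ctx_rh_G_occipital_sup,R,cortical
12121,ctx_rh_G_oc-temp_lat-fusifor,R,cortical
12122,ctx_rh_G_oc-temp_med-Lingual,R,cortical
12123,ctx_rh_G_oc-temp_med-Parahip,R,cortical
12124,ctx_rh_G_orbital,R,cortical
12125,ctx_rh_G_pariet_inf-Angular,R,cortical
12126,ctx_rh_G_pariet_inf-Supramar,R,cortical
12127,ctx_rh_G_parietal_sup,R,cortical
12128,ctx_rh_G_postcentral,R,cortical
12129,ctx_rh_G_precentral,R,cortical
12130,ctx_rh_G_precuneus,R,cortical
12131,ctx_rh_G_rectus,R,cortical
12132,ctx_rh_G_subcallosal,R,cortical
12133,ctx_rh_G_temp_sup-G_T_transv,R,cortical
12134,ctx_rh_G_temp_sup-Lateral,R,cortical
12135,ctx_rh_G_temp_sup-Plan_polar,R,cortical
12136,ctx_rh_G_temp_sup-Plan_tempo,R,cortical
12137,ctx_rh_G_temporal_inf,R,cortical
12138,ctx_rh_G_temporal_middle,R,cortical
12139,ctx_rh_Lat_Fis-ant-Horizont,R,cortical
12140,ctx_rh_Lat_Fis-ant-Vertical,R,cortical
12141,ctx_rh_Lat_Fis-post,R,cortical
12142,ctx_rh_Pole_occipital,R,cortical
12143,ctx_rh_Pole_temporal,R,cortical
12144,ctx_rh_S_calcarine,R,cortical
12145,ctx_rh_S_central,R,cortical
12146,ctx_rh_S_cingul-Marginalis,R,cortical
12147,ctx_rh_S_circular_insula_ant,R,cortical
12148,ctx_rh_S_circular_insula_inf,R,cortical
12149,ctx_rh_S_circular_insula_sup,R,cortical
12150,ctx_rh_S_collat_transv_ant,R,cortical
12151,ctx_rh_S_collat_transv_post,R,cortical
12152,ctx_rh_S_front_inf,R,cortical
12153,ctx_rh_S_front_middle,R,cortical
12154,ctx_rh_S_front_sup,R,cortical
12155,ctx_rh_S_interm_prim-Jensen,R,cortical
12156,ctx_rh_S_intrapariet_and_P_trans,R,cortical
12157,ctx_rh_S_oc_middle_and_Lunatus,R,cortical
12158,ctx_rh_S_oc_sup_and_transversal,R,cortical
12159,ctx_rh_S_occipital_ant,R,cortical
12160,ctx_rh_S_oc-temp_lat,R,cortical
12161,ctx_rh_S_oc-temp_med_and_Lingual,R,cortical
12162,ctx_rh_S_orbital_lateral,R,cortical
12163,ctx_rh_S_orbital_med-olfact,R,cortical
12164,ctx_rh_S_orbital-H_Shaped,R,cortical
12165,ctx_rh_S_parieto_occipital,R,cortical
12166,ctx_rh_S_pericallosal,R,cortical
12167,ctx_rh_S_postcentral,R,cortical
12168,ctx_rh_S_precentral-inf-part,R,cortical
12169,ctx_rh_S_precentral-sup-part,R,cortical
12170,ctx_rh_S_suborbital,R,cortical
12171,ctx_rh_S_subparietal,R,cortical
12172,ctx_rh_S_temporal_inf,R,cortical
12173,ctx_rh_S_temporal_sup,R,cortical
12174,ctx_rh_S_temporal_transverse,R,cortical
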