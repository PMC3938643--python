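# Synthetic reconstruction of the published eukaryote-wide survey of
# elongation-factor presence/absence (eEF1A, eEF1Balpha, EFL). Named rows
# encode every exception the survey reports in prose (co-maintainers,
# genes caught mid-decay); the *_sp_* rows are synthetic placeholders for
# the bulk mutually-exclusive pattern at realistic proportions. Not the
# original supplementary table.
taxon	lineage	eEF1A	eEF1Ba	EFL
Thalassiosira_pseudonana	Stramenopiles	present	absent	present
Karenia_brevis	Alveolata	present	absent	present
Symbiodinium_sp	Alveolata	present	absent	present
Ulva_prolifera	Viridiplantae	present	absent	present
Guillardia_theta	Cryptophyta	present	divergent	present
Pythium_ultimum	Stramenopiles	absent	divergent	present
Allomyces_macrogynus	Fungi	divergent	absent	present
Aspergillus_niger	Fungi	divergent	absent	present
Pseudo-nitzschia_multiseries	Stramenopiles	divergent	absent	present
Fragilariopsis_cylindrus	Stramenopiles	divergent	absent	present
Bigelowiella_natans	Rhizaria	divergent	absent	present
Chlamydomonas_reinhardtii	Viridiplantae	divergent	absent	present
Volvox_carteri	Viridiplantae	divergent	absent	present
Thecamonas_trahens	Apusozoa	present	present	divergent
Monosiga_brevicollis	Choanoflagellatea	absent	absent	present
EFL_only_sp_01	synthetic_clade_1	absent	absent	present
EFL_only_sp_02	synthetic_clade_2	absent	absent	present
EFL_only_sp_03	synthetic_clade_3	absent	absent	present
EFL_only_sp_04	synthetic_clade_4	absent	absent	present
EFL_only_sp_05	synthetic_clade_5	absent	absent	present
EFL_only_sp_06	synthetic_clade_6	absent	absent	present
EFL_only_sp_07	synthetic_clade_7	absent	absent	present
EFL_only_sp_08	synthetic_clade_8	absent	absent	present
EFL_only_sp_09	synthetic_clade_1	absent	absent	present
EFL_only_sp_10	synthetic_clade_2	absent	absent	present
EFL_only_sp_11	synthetic_clade_3	absent	absent	present
EFL_only_sp_12	synthetic_clade_4	absent	absent	present
EFL_only_sp_13	synthetic_clade_5	absent	absent	present
EFL_only_sp_14	synthetic_clade_6	absent	absent	present
EFL_only_sp_15	synthetic_clade_7	absent	absent	present
EFL_only_sp_16	synthetic_clade_8	absent	absent	present
EFL_only_sp_17	synthetic_clade_1	absent	absent	present
EFL_only_sp_18	synthetic_clade_2	absent	absent	present
EFL_only_sp_19	synthetic_clade_3	absent	absent	present
EFL_only_sp_20	synthetic_clade_4	absent	absent	present
EFL_only_sp_21	synthetic_clade_5	absent	absent	present
EFL_only_sp_22	synthetic_clade_6	absent	absent	present
EFL_only_sp_23	synthetic_clade_7	absent	absent	present
EFL_only_sp_24	synthetic_clade_8	absent	absent	present
EFL_only_sp_25	synthetic_clade_1	absent	absent	present
EFL_only_sp_26	synthetic_clade_2	absent	absent	present
EFL_only_sp_27	synthetic_clade_3	absent	absent	present
EFL_only_sp_28	synthetic_clade_4	absent	absent	present
EFL_only_sp_29	synthetic_clade_5	absent	absent	present
EFL_only_sp_30	synthetic_clade_6	absent	absent	present
EFL_only_sp_31	synthetic_clade_7	absent	absent	present
EFL_only_sp_32	synthetic_clade_8	absent	absent	present
EFL_only_sp_33	synthetic_clade_1	absent	absent	present
EFL_only_sp_34	synthetic_clade_2	absent	absent	present
EFL_only_sp_35	synthetic_clade_3	absent	absent	present
EFL_only_sp_36	synthetic_clade_4	absent	absent	present
EFL_only_sp_37	synthetic_clade_5	absent	absent	present
EFL_only_sp_38	synthetic_clade_6	absent	absent	present
EFL_only_sp_39	synthetic_clade_7	absent	absent	present
EFL_only_sp_40	synthetic_clade_8	absent	absent	present
EFL_only_sp_41	synthetic_clade_1	absent	absent	present
EFL_only_sp_42	synthetic_clade_2	absent	absent	present
EFL_only_sp_43	synthetic_clade_3	absent	absent	present
EFL_only_sp_44	synthetic_clade_4	absent	absent	present
EFL_only_sp_45	synthetic_clade_5	absent	absent	present
EFL_only_sp_46	synthetic_clade_6	absent	absent	present
EFL_only_sp_47	synthetic_clade_7	absent	absent	present
EFL_only_sp_48	synthetic_clade_8	absent	absent	present
EFL_only_sp_49	synthetic_clade_1	absent	absent	present
EFL_only_sp_50	synthetic_clade_2	absent	absent	present
eEF1A_sp_01	synthetic_clade_1	present	present	absent
eEF1A_sp_02	synthetic_clade_2	present	present	absent
eEF1A_sp_03	synthetic_clade_3	present	present	absent
eEF1A_sp_04	synthetic_clade_4	present	present	absent
eEF1A_sp_05	synthetic_clade_5	present	present	absent
eEF1A_sp_06	synthetic_clade_6	present	present	absent
eEF1A_sp_07	synthetic_clade_7	present	present	absent
eEF1A_sp_08	synthetic_clade_8	present	present	absent
eEF1A_sp_09	synthetic_clade_1	present	present	absent
eEF1A_sp_10	synthetic_clade_2	present	present	absent
eEF1A_sp_11	synthetic_clade_3	present	present	absent
eEF1A_sp_12	synthetic_clade_4	present	present	absent
eEF1A_sp_13	synthetic_clade_5	present	present	absent
eEF1A_sp_14	synthetic_clade_6	present	present	absent
eEF1A_sp_15	synthetic_clade_7	present	present	absent
eEF1A_sp_16	synthetic_clade_8	present	present	absent
eEF1A_sp_17	synthetic_clade_1	present	present	absent
eEF1A_sp_18	synthetic_clade_2	present	present	absent
eEF1A_sp_19	synthetic_clade_3	present	present	absent
eEF1A_sp_20	synthetic_clade_4	present	present	absent
eEF1A_sp_21	synthetic_clade_5	present	present	absent
eEF1A_sp_22	synthetic_clade_6	present	present	absent
eEF1A_sp_23	synthetic_clade_7	present	present	absent
eEF1A_sp_24	synthetic_clade_8	present	present	absent
eEF1A_sp_25	synthetic_clade_1	present	present	absent
eEF1A_sp_26	synthetic_clade_2	present	present	absent
eEF1A_sp_27	synthetic_clade_3	present	present	absent
eEF1A_sp_28	synthetic_clade_4	present	present	absent
eEF1A_sp_29	synthetic_clade_5	present	present	absent
eEF1A_sp_30	synthetic_clade_6	present	present	absent
eEF1A_sp_31	synthetic_clade_7	present	present	absent
eEF1A_sp_32	synthetic_clade_8	present	present	absent
eEF1A_sp_33	synthetic_clade_1	present	present	absent
eEF1A_sp_34	synthetic_clade_2	present	present	absent
eEF1A_sp_35	synthetic_clade_3	present	present	absent
eEF1A_sp_36	synthetic_clade_4	present	present	absent
eEF1A_sp_37	synthetic_clade_5	present	present	absent
eEF1A_sp_38	synthetic_clade_6	present	present	absent
eEF1A_sp_39	synthetic_clade_7	present	present	absent
eEF1A_sp_40	synthetic_clade_8	present	present	absent
eEF1A_sp_41	synthetic_clade_1	present	present	absent
eEF1A_sp_42	synthetic_clade_2	present	present	absent
eEF1A_sp_43	synthetic_clade_3	present	present	absent
eEF1A_sp_44	synthetic_clade_4	present	present	absent
eEF1A_sp_45	synthetic_clade_5	present	present	absent
eEF1A_sp_46	synthetic_clade_6	present	present	absent
eEF1A_sp_47	synthetic_clade_7	present	present	absent
eEF1A_sp_48	synthetic_clade_8	present	present	absent
eEF1A_sp_49	synthetic_clade_1	present	present	absent
eEF1A_sp_50	synthetic_clade_2	present	present	absent
eEF1A_sp_51	synthetic_clade_3	present	present	absent
eEF1A_sp_52	synthetic_clade_4	present	present	absent
eEF1A_sp_53	synthetic_clade_5	present	present	absent
eEF1A_sp_54	synthetic_clade_6	present	present	absent
eEF1A_sp_55	synthetic_clade_7	present	present	absent
eEF1A_sp_56	synthetic_clade_8	present	present	absent
eEF1A_sp_57	synthetic_clade_1	present	present	absent
eEF1A_sp_58	synthetic_clade_2	present	present	absent
eEF1A_sp_59	synthetic_clade_3	present	present	absent
eEF1A_sp_60	synthetic_clade_4	present	present	absent
eEF1A_sp_61	synthetic_clade_5	present	present	absent
eEF1A_sp_62	synthetic_clade_6	present	present	absent
eEF1A_sp_63	synthetic_clade_7	present	present	absent
eEF1A_sp_64	synthetic_clade_8	present	present	absent
eEF1A_sp_65	synthetic_clade_1	present	present	absent
eEF1A_sp_66	synthetic_clade_2	present	present	absent
eEF1A_sp_67	synthetic_clade_3	present	present	absent
eEF1A_sp_68	synthetic_clade_4	present	present	absent
eEF1A_sp_69	synthetic_clade_5	present	present	absent
eEF1A_sp_70	synthetic_clade_6	present	present	absent
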