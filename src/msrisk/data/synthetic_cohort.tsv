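sample_id	label	HLA_DRB1_1501	rs_fix_0001	rs_fix_0002
case_01	case	1	1	2
case_02	case	0	1	1
case_03	case	2	1	2
case_04	case	2	1	1
case_05	case	0	1	1
case_06	case	NA	1	2
case_07	case	1	0	1
case_08	case	1	1	1
case_09	case	NA	0	1
case_10	case	0	1	1
case_11	case	1	1	2
case_12	case	1	1	1
case_13	case	1	0	1
case_14	case	1	1	2
case_15	case	1	2	2
case_16	case	0	0	2
case_17	case	1	1	1
case_18	case	1	0	2
case_19	case	2	1	2
case_20	case	0	1	1
case_21	case	1	1	2
case_22	case	2	1	1
case_23	case	1	0	2
case_24	case	0	1	0
case_25	case	2	1	2
case_26	case	2	2	NA
case_27	case	1	0	0
case_28	case	1	1	1
case_29	case	2	1	2
case_30	case	1	2	2
case_31	case	1	1	2
case_32	case	1	1	1
case_33	case	NA	1	1
case_34	case	1	2	1
case_35	case	1	0	2
case_36	case	0	2	1
case_37	case	1	0	1
case_38	case	2	NA	1
case_39	case	1	1	1
case_40	case	1	1	1
case_41	case	1	1	1
case_42	case	1	0	2
case_43	case	2	1	1
case_44	case	2	0	2
case_45	case	1	0	2
case_46	case	1	0	0
case_47	case	0	2	1
case_48	case	0	0	0
case_49	case	2	1	2
case_50	case	2	0	2
case_51	case	1	0	1
case_52	case	1	0	2
case_53	case	1	0	1
case_54	case	NA	0	1
case_55	case	1	1	2
case_56	case	1	1	2
case_57	case	1	1	NA
case_58	case	0	2	1
case_59	case	2	0	2
case_60	case	2	1	1
case_61	case	1	0	1
case_62	case	1	2	2
case_63	case	0	1	1
case_64	case	1	0	2
case_65	case	1	2	1
case_66	case	2	1	2
case_67	case	NA	2	1
case_68	case	1	0	2
case_69	case	1	1	NA
case_70	case	1	1	1
control_01	control	0	0	NA
control_02	control	1	0	1
control_03	control	2	0	1
control_04	control	1	1	NA
control_05	control	0	1	2
control_06	control	1	0	2
control_07	control	1	0	2
control_08	control	0	0	2
control_09	control	0	0	2
control_10	control	0	0	1
control_11	control	1	1	1
control_12	control	0	0	2
control_13	control	1	1	NA
control_14	control	0	2	1
control_15	control	1	1	2
control_16	control	1	1	1
control_17	control	0	1	2
control_18	control	0	1	1
control_19	control	0	0	1
control_20	control	0	0	2
control_21	control	0	0	1
control_22	control	0	0	2
control_23	control	NA	0	2
control_24	control	0	0	1
control_25	control	0	0	0
control_26	control	0	0	1
control_27	control	1	1	NA
control_28	control	0	NA	2
control_29	control	0	1	1
control_30	control	1	0	2
control_31	control	0	0	1
control_32	control	0	1	1
control_33	control	0	1	1
control_34	control	0	2	1
control_35	control	0	0	1
control_36	control	1	0	1
control_37	control	1	NA	1
control_38	control	0	1	NA
control_39	control	0	0	NA
control_40	control	1	0	2
control_41	control	0	0	2
control_42	control	0	0	2
control_43	control	0	1	NA
control_44	control	0	0	2
control_45	control	0	0	0
control_46	control	1	1	1
control_47	control	1	2	0
control_48	control	0	0	2
control_49	control	0	0	2
control_50	control	0	0	1
control_51	control	2	1	2
control_52	control	0	0	2
control_53	control	0	0	2
control_54	control	2	0	1
control_55	control	0	2	1
control_56	control	2	0	0
control_57	control	0	1	0
control_58	control	1	1	1
control_59	control	0	0	2
control_60	control	0	2	1
control_61	control	0	0	1
control_62	control	0	0	0
control_63	control	0	0	1
control_64	control	0	0	2
control_65	control	0	0	1
control_66	control	2	1	1
control_67	control	0	2	1
control_68	control	0	NA	1
control_69	control	0	1	0
control_70	control	0	1	2
control_71	control	1	1	1
control_72	control	0	0	1
control_73	control	0	1	1
control_74	control	0	2	1
control_75	control	1	0	1
control_76	control	0	1	1
control_77	control	1	0	2
control_78	control	0	0	1
control_79	control	0	NA	2
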