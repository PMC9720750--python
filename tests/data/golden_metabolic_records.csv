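individual_id,site,temp_level_c,dry_mass_mg,length_mm,vo2_umol_per_h,smr_j_per_day,mass_specific_smr,so2_umol_per_l_torr,qc_flags
qua_8C_0000,Quarantia,8.0,1.90953,7.65647,0.05489047456051415,0.5928171252535528,0.31045185215919774,2.0633344821039104,specimen_drift;blank_drift
qua_8C_0001,Quarantia,8.0,0.465057,4.96518,0.02320013291677631,0.25056143550118415,0.5387757532973037,2.0633344821039104,specimen_drift
qua_18C_0002,Quarantia,18.0,4.06806,9.98401,0.16117718520861474,1.7407136002530392,0.4278977203514794,1.6813108696550831,specimen_drift;blank_drift
qua_18C_0003,Quarantia,18.0,8.68935,13.2293,0.32146394818066015,3.4718106403511295,0.3995477959054624,1.6813108696550831,specimen_drift;blank_drift
qua_25C_0004,Quarantia,25.0,0.652584,5.39296,0.059688551173896064,0.6446363526780775,0.9878212654280176,1.4921839356686892,specimen_drift;blank_drift
qua_25C_0005,Quarantia,25.0,10.7413,13.863,0.454711420095597,4.910883337032447,0.45719636701632455,1.4921839356686892,specimen_drift;blank_drift
qua_25.6C_0006,Quarantia,25.6,0.515439,4.94789,0.06613052865229688,0.7142097094448063,1.3856338178616798,1.478239642621082,specimen_drift;blank_drift
qua_25.6C_0007,Quarantia,25.6,0.644527,5.71528,0.0688782805000004,0.7438854294000043,1.1541571251475957,1.478239642621082,specimen_drift;blank_drift
qua_26.2C_0008,Quarantia,26.2,5.53441,11.0268,0.26391911163388915,2.850326405646003,0.5150190184041303,1.4646127222503402,specimen_drift;blank_drift
qua_26.2C_0009,Quarantia,26.2,9.21088,13.3347,0.46035355578719345,4.97181840250169,0.5397766991320797,1.4646127222503402,specimen_drift;blank_drift
les_11C_0010,Lesina,11.0,2.06754,7.97663,0.05879909605131978,0.6350302373542536,0.3071429028479514,1.907253384820862,specimen_drift;blank_drift
les_11C_0011,Lesina,11.0,10.6048,13.4031,0.19677743492279956,2.125196297166235,0.20039946978408224,1.907253384820862,specimen_drift;blank_drift
les_18C_0012,Lesina,18.0,1.59782,6.71249,0.0688712186556526,0.743809161481048,0.4655149900996658,1.6612286809699568,specimen_drift;blank_drift
les_18C_0013,Lesina,18.0,1.15326,6.74744,0.0667674386540721,0.7210883374639787,0.6252608583181405,1.6612286809699568,specimen_drift;blank_drift
les_28C_0014,Lesina,28.0,1.12636,6.59913,0.10805214792249401,1.1669631975629353,1.0360481529554808,1.4096896516419424,specimen_drift;blank_drift
les_28C_0015,Lesina,28.0,7.05959,12.1021,0.2898389588879116,3.130260755989446,0.4434054606555687,1.4096896516419424,specimen_drift;blank_drift
les_28.6C_0016,Lesina,28.6,6.9596,11.8799,0.31403640684693046,3.391593193946849,0.4873258799279914,1.3974589081100652,specimen_drift;blank_drift
les_28.6C_0017,Lesina,28.6,11.5187,14.4115,0.4829980207777366,5.216378624399555,0.45286174866951606,1.3974589081100652,specimen_drift
les_29.2C_0018,Lesina,29.2,1.03032,6.34655,0.10959284950707851,1.183602774676448,1.1487720074117245,1.3855044716670974,specimen_drift;blank_drift
les_29.2C_0019,Lesina,29.2,4.27592,10.6416,0.3004205971969428,3.244542449726983,0.7587940021625715,1.3855044716670974,specimen_drift;blank_drift
acq_12C_0020,Acquatina,12.0,4.61692,10.3455,0.14370467443345603,1.552010483881325,0.3361571099090573,1.879396551981294,specimen_drift;blank_drift
acq_12C_0021,Acquatina,12.0,6.41861,11.6409,0.14050819677784684,1.517488525200746,0.23642011669204796,1.879396551981294,blank_drift
acq_18C_0022,Acquatina,18.0,2.80417,9.39058,0.1395184682810523,1.5067994574353651,0.5373424069993492,1.6712401269860873,specimen_drift;blank_drift
acq_18C_0023,Acquatina,18.0,8.34095,12.8734,0.2301631902885235,2.485762455116054,0.29801910515181773,1.6712401269860873,specimen_drift;blank_drift
acq_27C_0024,Acquatina,27.0,6.19514,11.3776,0.259289424742604,2.8003257872201237,0.45201977472988886,1.438792634183312,blank_drift
acq_27C_0025,Acquatina,27.0,1.43224,6.77856,0.12316180052019901,1.3301474456181492,0.9287182634322105,1.438792634183312,specimen_drift;blank_drift
acq_27.6C_0026,Acquatina,27.6,0.748785,5.58784,0.08930981718391737,0.9645460255863075,1.288148167479727,1.4259819062933872,specimen_drift;blank_drift
acq_27.6C_0027,Acquatina,27.6,1.82323,7.76575,0.13891174220518918,1.5002468158160431,0.8228511026124203,1.4259819062933872,specimen_drift;blank_drift
acq_28.2C_0028,Acquatina,28.2,2.23007,8.27284,0.20336313529371752,2.1963218611721493,0.9848667804921591,1.4134611421899261,specimen_drift;blank_drift
acq_28.2C_0029,Acquatina,28.2,12.5425,14.2914,0.3930496205756062,4.244935902216547,0.33844416202643385,1.4134611421899261,specimen_drift;blank_drift
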