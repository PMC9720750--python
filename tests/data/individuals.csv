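individual_id,site,chamber_id,run_id,temp_level_c,dry_mass_mg,length_mm
qua_8C_0000,Quarantia,ch1,run0001,8,1.90953,7.65647
qua_8C_0001,Quarantia,ch2,run0001,8,0.465057,4.96518
qua_18C_0002,Quarantia,ch1,run0002,18,4.06806,9.98401
qua_18C_0003,Quarantia,ch2,run0002,18,8.68935,13.2293
qua_25C_0004,Quarantia,ch1,run0003,25,0.652584,5.39296
qua_25C_0005,Quarantia,ch2,run0003,25,10.7413,13.863
qua_25.6C_0006,Quarantia,ch1,run0004,25.6,0.515439,4.94789
qua_25.6C_0007,Quarantia,ch2,run0004,25.6,0.644527,5.71528
qua_26.2C_0008,Quarantia,ch1,run0005,26.2,5.53441,11.0268
qua_26.2C_0009,Quarantia,ch2,run0005,26.2,9.21088,13.3347
les_11C_0010,Lesina,ch1,run0006,11,2.06754,7.97663
les_11C_0011,Lesina,ch2,run0006,11,10.6048,13.4031
les_18C_0012,Lesina,ch1,run0007,18,1.59782,6.71249
les_18C_0013,Lesina,ch2,run0007,18,1.15326,6.74744
les_28C_0014,Lesina,ch1,run0008,28,1.12636,6.59913
les_28C_0015,Lesina,ch2,run0008,28,7.05959,12.1021
les_28.6C_0016,Lesina,ch1,run0009,28.6,6.9596,11.8799
les_28.6C_0017,Lesina,ch2,run0009,28.6,11.5187,14.4115
les_29.2C_0018,Lesina,ch1,run0010,29.2,1.03032,6.34655
les_29.2C_0019,Lesina,ch2,run0010,29.2,4.27592,10.6416
acq_12C_0020,Acquatina,ch1,run0011,12,4.61692,10.3455
acq_12C_0021,Acquatina,ch2,run0011,12,6.41861,11.6409
acq_18C_0022,Acquatina,ch1,run0012,18,2.80417,9.39058
acq_18C_0023,Acquatina,ch2,run0012,18,8.34095,12.8734
acq_27C_0024,Acquatina,ch1,run0013,27,6.19514,11.3776
acq_27C_0025,Acquatina,ch2,run0013,27,1.43224,6.77856
acq_27.6C_0026,Acquatina,ch1,run0014,27.6,0.748785,5.58784
acq_27.6C_0027,Acquatina,ch2,run0014,27.6,1.82323,7.76575
acq_28.2C_0028,Acquatina,ch1,run0015,28.2,2.23007,8.27284
acq_28.2C_0029,Acquatina,ch2,run0015,28.2,12.5425,14.2914
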