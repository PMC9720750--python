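# Synthetic fixture data

All files here are synthetic, produced by `thermoscale.synth` at a fixed seed
(30 individuals, 60 s sampling, AR(1) electrode noise, equilibration
transient). `golden_metabolic_records.csv` is the respirometry-stage output of
the first verified run over these inputs and anchors the golden-file
regression test.
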