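# tool_version: 0.1.0
# generator_seed: 777
# source_label: synthetic doubling-dilution distribution (generated fixture, not EUCAST data)
pathogen,mic_mg_l,count
Escherichia coli,0.001953125,3
Escherichia coli,0.00390625,44
Escherichia coli,0.0078125,467
Escherichia coli,0.015625,992
Escherichia coli,0.03125,446
Escherichia coli,0.0625,48
Klebsiella pneumoniae,0.00390625,7
Klebsiella pneumoniae,0.0078125,118
Klebsiella pneumoniae,0.015625,456
Klebsiella pneumoniae,0.03125,810
Klebsiella pneumoniae,0.0625,501
Klebsiella pneumoniae,0.125,98
Klebsiella pneumoniae,0.25,9
Klebsiella pneumoniae,0.5,1
Streptococcus pneumoniae,0.001953125,2
Streptococcus pneumoniae,0.00390625,23
Streptococcus pneumoniae,0.0078125,171
Streptococcus pneumoniae,0.015625,485
Streptococcus pneumoniae,0.03125,638
Streptococcus pneumoniae,0.0625,482
Streptococcus pneumoniae,0.125,175
Streptococcus pneumoniae,0.25,22
Streptococcus pneumoniae,0.5,2
Haemophilus influenzae,0.00390625,1
Haemophilus influenzae,0.0078125,11
Haemophilus influenzae,0.015625,88
Haemophilus influenzae,0.03125,482
Haemophilus influenzae,0.0625,798
Haemophilus influenzae,0.125,496
Haemophilus influenzae,0.25,107
Haemophilus influenzae,0.5,17
Enterobacter cloacae,0.001953125,1
Enterobacter cloacae,0.00390625,29
Enterobacter cloacae,0.0078125,169
Enterobacter cloacae,0.015625,481
Enterobacter cloacae,0.03125,680
Enterobacter cloacae,0.0625,454
Enterobacter cloacae,0.125,151
Enterobacter cloacae,0.25,34
Enterobacter cloacae,0.5,1
Serratia marcescens,0.0078125,7
Serratia marcescens,0.015625,102
Serratia marcescens,0.03125,499
Serratia marcescens,0.0625,791
Serratia marcescens,0.125,476
Serratia marcescens,0.25,119
Serratia marcescens,0.5,6
Pseudomonas aeruginosa,0.015625,10
Pseudomonas aeruginosa,0.03125,46
Pseudomonas aeruginosa,0.0625,125
Pseudomonas aeruginosa,0.125,247
Pseudomonas aeruginosa,0.25,356
Pseudomonas aeruginosa,0.5,445
Pseudomonas aeruginosa,1.0,372
Pseudomonas aeruginosa,2.0,223
Pseudomonas aeruginosa,4.0,113
Pseudomonas aeruginosa,8.0,48
Pseudomonas aeruginosa,16.0,8
Pseudomonas aeruginosa,32.0,7
Acinetobacter baumannii,0.00390625,6
Acinetobacter baumannii,0.0078125,11
Acinetobacter baumannii,0.015625,59
Acinetobacter baumannii,0.03125,139
Acinetobacter baumannii,0.0625,242
Acinetobacter baumannii,0.125,332
Acinetobacter baumannii,0.25,417
Acinetobacter baumannii,0.5,384
Acinetobacter baumannii,1.0,221
Acinetobacter baumannii,2.0,120
Acinetobacter baumannii,4.0,50
Acinetobacter baumannii,8.0,14
Acinetobacter baumannii,16.0,5
Staphylococcus aureus,0.00390625,1
Staphylococcus aureus,0.0078125,15
Staphylococcus aureus,0.015625,84
Staphylococcus aureus,0.03125,232
Staphylococcus aureus,0.0625,438
Staphylococcus aureus,0.125,501
Staphylococcus aureus,0.25,436
Staphylococcus aureus,0.5,205
Staphylococcus aureus,1.0,79
Staphylococcus aureus,2.0,7
Staphylococcus aureus,4.0,2
Enterococcus faecalis,0.125,3
Enterococcus faecalis,0.25,13
Enterococcus faecalis,0.5,71
Enterococcus faecalis,1.0,236
Enterococcus faecalis,2.0,408
Enterococcus faecalis,4.0,542
Enterococcus faecalis,8.0,420
Enterococcus faecalis,16.0,213
Enterococcus faecalis,32.0,72
Enterococcus faecalis,64.0,19
Enterococcus faecalis,128.0,3
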