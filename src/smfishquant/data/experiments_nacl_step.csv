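experiment,condition,replicate,timepoints_min,n_stacks,fields_per_timepoint
Exp1_rep1,0.2 M NaCl step,1,0 1 2 4 6 8 10 15 20 25 30 35 40 45 50 55,63,4
Exp1_rep2,0.2 M NaCl step,2,0 1 2 4 6 8 10 15 20 25 30 35 40 45 50 55,64,4
Exp2_rep1,0.4 M NaCl step,1,0 1 2 4 6 8 10 15 20 25 30 35 40 45 50 55,72,4
Exp2_rep2,0.4 M NaCl step,2,0 1 2 4 6 8 10 15 20 25 30 35 40 45 50 55 60,71,4
Exp2_rep3,0.4 M NaCl step,3,0 2 4 6 8 10 15 20 25 30 35 40 45 50 55,67,4
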