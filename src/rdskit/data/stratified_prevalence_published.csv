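window,trait,n_total,pct_total,ci_lo,ci_hi,n_early,pct_early,ci_lo_early,ci_hi_early,n_late,pct_late,ci_lo_late,ci_hi_late,ratio,p_printed
lifetime,ketamine,162,11.7,9.3,14.8,125,16.3,13.0,21.5,37,5.7,3.3,8.6,2.9,<0.001
lifetime,ecstasy,146,11.7,8.8,14.9,105,15.0,11.2,19.6,41,7.5,3.8,11.1,2.0,<0.001
lifetime,marijuana,152,10.5,8.0,13.4,104,13.6,9.7,18.1,48,6.4,4.0,9.4,2.1,<0.001
lifetime,methamphetamine,79,6.0,3.6,8.5,64,10.2,6.6,14.8,15,2.7,0.9,4.9,3.8,<0.001
lifetime,heroin,43,2.7,1.0,4.6,34,4.3,1.7,7.9,9,1.1,0.2,2.8,3.9,<0.001
lifetime,any_illegal,277,21.2,17.3,25.0,206,28.8,23.7,34.1,71,11.5,7.3,15.8,2.5,<0.001
lifetime,any_club,245,18.0,14.6,21.3,180,23.6,19.1,28.4,65,10.6,6.6,14.5,2.2,<0.001
lifetime,any_hard,85,6.5,3.9,9.0,70,11.1,7.0,15.5,15,2.7,1.0,4.8,4.1,<0.001
lifetime,single_drug,103,8.2,5.9,10.3,79,6.1,4.1,7.6,24,2.0,0.8,3.5,3.1,<0.001
lifetime,poly_no_hard,104,7.6,5.7,10.3,72,5.6,4.0,8.0,32,2.0,1.1,3.1,2.8,0.001
lifetime,poly_hard,70,5.2,2.9,7.4,55,4.9,2.9,7.4,15,1.1,0.3,1.9,4.5,<0.001
past_year,ketamine,67,4.3,2.8,6.2,47,5.6,3.5,8.6,20,2.9,0.9,5.0,1.9,0.023
past_year,ecstasy,53,4.0,2.2,6.1,32,3.8,2.1,6.4,21,4.1,1.2,7.6,0.9,0.800
past_year,marijuana,56,3.8,2.3,5.7,33,4.7,2.4,7.2,23,2.7,1.4,4.8,1.7,0.074
past_year,methamphetamine,29,2.9,1.5,4.7,22,4.4,2.2,7.3,7,1.9,0.3,4.0,2.3,0.015
past_year,heroin,22,0.9,0.2,2.3,16,1.0,0.1,3.1,6,0.7,0.0,2.0,1.4,0.585
past_year,any_illegal,130,8.9,6.3,12.0,90,11.1,7.9,15.4,40,6.4,3.2,10.0,1.7,0.005
past_year,any_club,103,7.0,4.8,9.5,69,8.0,5.3,11.2,34,5.5,2.5,9.1,1.5,0.095
past_year,any_hard,42,3.2,1.7,5.4,31,4.9,2.6,8.4,11,2.0,0.5,4.0,2.5,0.007
past_year,single_drug,63,4.5,2.7,6.6,50,3.5,2.2,5.3,13,1.1,0.2,2.4,3.2,0.006
past_year,poly_no_hard,44,3.0,1.7,4.8,26,2.0,1.0,3.4,18,1.0,0.3,1.8,2.0,0.163
past_year,poly_hard,26,1.8,0.8,3.0,17,1.2,0.4,2.2,9,0.7,0.2,1.4,1.7,0.385
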