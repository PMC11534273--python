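item_id,phase,sure_true,unsure_true,unsure_false,sure_false,true_pct,false_pct
q1,pre,11,27,36,26,38,62
q1,post,22,11,11,55,33,66
q2,pre,28,45,19,7,73,27
q2,post,66,22,6,5,88,11
q3,pre,11,17,30,42,28,72
q3,post,18,8,12,63,26,75
q4,pre,6,16,21,57,22,78
q4,post,14,7,5,75,21,80
q5,pre,7,40,37,16,47,53
q5,post,18,15,6,61,33,67
q6,pre,17,39,29,15,56,44
q6,post,31,13,13,42,44,55
q7,pre,8,51,30,11,59,41
q7,post,36,20,11,33,56,44
q8,pre,9,30,31,30,38,62
q8,post,16,10,14,60,26,74
q9,pre,35,58,6,1,93,7
q9,post,73,20,3,4,93,7
q10,pre,16,38,34,12,54,46
q10,post,35,21,18,26,56,44
q11,pre,7,27,41,24,35,65
q11,post,21,12,17,50,33,67
q12,pre,29,58,9,4,87,13
q12,post,63,17,5,15,80,20
q13,pre,32,56,10,3,88,12
q13,post,79,17,2,2,96,4
q14,pre,36,57,6,2,93,7
q14,post,81,17,2,1,98,3
q15,pre,22,63,13,3,84,16
q15,post,64,26,6,4,90,10
q16,pre,11,23,35,31,34,66
q16,post,16,11,12,61,27,73
q17,pre,57,29,12,2,86,14
q17,post,87,9,2,3,96,5
q18,pre,32,58,8,1,91,9
q18,post,76,21,2,1,97,3
q19,pre,26,58,14,3,84,16
q19,post,63,26,7,5,89,12
q20,pre,22,42,28,8,64,36
q20,post,38,19,19,25,57,44
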