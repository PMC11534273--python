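item_id,mcnemar_stat,mcnemar_p,change_printed
q1,2.47,.16,100
q2,26.18,<.001,-28.5
q3,1.25,.26,64
q4,0.91,.34,5
q5,16.20,<.001,129
q6,13.23,<.001,82
q7,0.81,.37,350
q8,19.76,<.001,-32
q9,0.02,.88,300
q10,0.15,.70,4
q11,0.38,.54,-6
q12,8.56,.003,117
q13,18.67,<.001,-33
q14,9.14,.003,-50
q15,4.41,.04,191
q16,6.86,.009,45
q17,14.29,<.001,50
q18,10.12,.002,0
q19,2.06,.15,67
q20,6.88,.009,73
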