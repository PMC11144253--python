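# Default hypoglycemia rule grammar: boolean conditions over lagged
# glucose/heart-rate/steps/calorie variables with digit-encoded constants.
<cond> ::= <rel> | ( <cond> && <cond> ) | ( <cond> || <cond> )
<rel> ::= <aexpr> <relop> <aexpr>
<relop> ::= < | > | <= | >=
<aexpr> ::= <operand> | ( <aexpr> <numop> <aexpr> )
<numop> ::= + | - | * | /
<operand> ::= <var> | <const>
<var> ::= gluc_0 | gluc_5 | gluc_10 | gluc_15 | gluc_20 | gluc_25 | hr_0 | hr_15 | hr_30 | hr_60 | hr_90 | hr_120 | steps_0 | steps_15 | steps_30 | steps_60 | steps_90 | steps_120 | cal_0 | cal_15 | cal_30 | cal_60 | cal_90 | cal_120
<const> ::= <gconst> | <uconst>
<gconst> ::= <digit> . <digit> <digit> <digit> | <digit> <digit> . <digit> <digit> <digit> | <hund> <digit> <digit> . <digit> <digit> <digit>
<uconst> ::= <digit> . <digit> <digit> <digit>
<digit> ::= 0 | 1 | 2 | 3 | 4 | 5 | 6 | 7 | 8 | 9
<hund> ::= 1 | 2 | 3
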