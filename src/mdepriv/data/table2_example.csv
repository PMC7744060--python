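respondent_id,financial_condition,employment_status,income_change,pay_bills,weight,group
1,1,4,4,2,1,A
2,2,1,3,1,1,A
3,4,5,5,2,1,B
4,3,1,4,1,1,B
5,2,2,5,1,1,B
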