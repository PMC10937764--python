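label,type,mean1,sd1,n1,mean2,sd2,n2
Mean age (years),summary,55.66,17.7,100,66.73,14.8,20
Mean inpatient duration (days),summary,3.76,7.14,100,6.11,5.20,20
Mean stone size (mm),summary,8.24,4.46,100,10.12,4.72,20
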