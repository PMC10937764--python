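code,descriptor,unit_cost_gbp
LB09D:NEL,"Non-Elective Intermediate Endoscopic Ureter Procedures, 19 years and over","£1,850.90"
LB65C–LB65E,"Elective Inpatient Major Endoscopic, Kidney or Ureter Procedures, 19 years and over","£2,854.44"
LB09D:FU,"Intermediate Ureter Procedures, 19 years and over",£171.42
RD40Z–RD42Z,Ultrasound Scan without Contrast,£65.54
RD23Z,"Computerised Tomography Scan of Two Areas, without Contrast",£123.90
PF,Plain Film,£33.61
LB72A,"Diagnostic Cystoscopy, 19 years and over",£171.38
LB75A,Percutaneous Nephrolithotomy with CC score 2+,"£7,202.79"
LB75B,Percutaneous Nephrolithotomy with CC score 0–1,"£2,546.12"
WF02C,"Multi-professional Non-Admitted Non-Face-to-Face Attendance, Follow-up",£77.56
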