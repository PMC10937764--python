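code,descriptor,unit_cost_gbp
LB65C–LB65E,"Non-Elective Major Endoscopic, Kidney or Ureter Procedures, 19 years and over","£3,402.12"
LB09D,"Intermediate Ureter Procedures, 19 years and over",£171.42
RD40Z–RD42Z,Ultrasound Scan without contrast,£65.64
RD23Z,"Computerised Tomography Scan of Two Areas, without Contrast",£123.9
PF,Plain Film,£33.61
RN25A,"Renogram, 19 years and older",£276.9
LB36Z,Extracorporeal Lithotripsy,£331.2
LB72A,"Diagnostic Cystoscopy, 19 years and over",£171.38
LB75A,Percutaneous Nephrolithotomy with CC score 2+,"£7,202.79"
LB75B,Percutaneous Nephrolithotomy with CC score 0–1,"£2,546.12"
WF02C,"Multi-professional Non-Admitted Non-Face-to-Face Attendance, Follow-up",£77.56
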