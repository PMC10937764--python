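label,type,x1,n1,x2,n2
Share of males,prop,73,100,11,20
Share of proximal ureteric stones,prop,33,100,8,20
Share of mid-ureteric stones,prop,16,100,7,20
Share of distal ureteric stones,prop,51,100,5,20
Complications,prop,4,100,1,20
Complete clearance,prop,66,100,14,20
Re-intervention,prop,9,100,3,20
Re-admission,prop,18,100,4,20
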