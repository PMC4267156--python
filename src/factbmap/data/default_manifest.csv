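item_id,subscale,negatively_worded
PWB1,PWB,true
PWB2,PWB,true
PWB3,PWB,true
PWB4,PWB,true
PWB5,PWB,true
PWB6,PWB,true
PWB7,PWB,true
SWB1,SWB,false
SWB2,SWB,false
SWB3,SWB,false
SWB4,SWB,false
SWB5,SWB,false
SWB6,SWB,false
SWB7,SWB,false
EWB1,EWB,true
EWB2,EWB,false
EWB3,EWB,true
EWB4,EWB,true
EWB5,EWB,true
EWB6,EWB,true
FWB1,FWB,false
FWB2,FWB,false
FWB3,FWB,false
FWB4,FWB,false
FWB5,FWB,false
FWB6,FWB,false
FWB7,FWB,false
BCS1,BCS,true
BCS2,BCS,true
BCS3,BCS,true
BCS4,BCS,false
BCS5,BCS,true
BCS6,BCS,false
BCS7,BCS,false
BCS8,BCS,true
BCS9,BCS,false
BCS10,BCS,false
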