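atpA
atpB
atpE
atpF
atpH
atpI
petA
petB
petD
petG
psaA
psaB
psaC
psaJ
psbA
psbB
psbC
psbD
psbE
psbF
psbH
psbI
psbJ
psbK
psbL
psbN
psbT
rbcL
rpl2
rpl14
rpl16
rpl20
rpl36
rpoA
rpoB
rpoC1
rpoC2
rps2
rps3
rps11
rps12
rps14
rps18
rps19
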