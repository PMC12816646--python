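atp4
atp6
atp8
atp9
cob
cox1
cox2
cox3
nad1
nad2
nad3
nad4
nad4L
nad5
nad6
nad7
nad9
nad11
rpl14
rpl16
rps3
rps4
rps12
rps14
tatC
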