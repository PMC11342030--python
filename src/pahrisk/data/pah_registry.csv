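abbreviation,full_name,n_rings,tef,carcinogenic,enabled
Naph,naphthalene,2,0.001,false,true
Acy,acenaphthylene,3,0.001,false,true
Acen,acenaphthene,3,0.001,false,true
Fln,fluorene,3,0.001,false,true
Phe,phenanthrene,3,0.001,false,true
Ant,anthracene,3,0.01,false,true
Flt,fluoranthene,4,0.001,false,true
Pyr,pyrene,4,0.001,false,true
BaA,benzo[a]anthracene,4,0.1,true,true
CHR,chrysene,4,0.01,true,true
BbF,benzo[b]fluoranthene,5,0.1,true,true
BkF,benzo[k]fluoranthene,5,0.1,true,true
BaP,benzo[a]pyrene,5,1.0,true,true
IcP,"indeno[1,2,3-cd]pyrene",6,0.1,true,true
DhA,"dibenzo[a,h]anthracene",5,1.0,true,true
BgP,"benzo[g,h,i]perylene",6,0.01,false,true
BeP,benzo[e]pyrene,5,0.0,false,false
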