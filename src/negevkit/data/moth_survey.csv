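site,country,lat,lon,species,stage,n,n_pos
Nuorgam,Finland,70.09155,27.89978,Epirrita autumnata,larva,1,0
Nuorgam,Finland,70.09155,27.89978,Epirrita autumnata,pupa,9,0
Nuorgam,Finland,70.09155,27.89978,Operophtera brumata,pupa,19,0
Utsjoki,Finland,69.87178,27.21863,Epirrita autumnata,pupa,6,0
Kilpisjarvi,Finland,69.06390,20.66048,Epirrita autumnata,pupa,18,0
Kilpisjarvi,Finland,69.06390,20.66048,Epirrita autumnata,adult,23,1
Neiden,Norway,69.67379,29.47426,Epirrita autumnata,pupa,12,0
Neiden,Norway,69.67379,29.47426,Operophtera brumata,pupa,22,0
Gratangen,Norway,68.72343,17.59460,Epirrita autumnata,pupa,33,0
Gratangen,Norway,68.72343,17.59460,Epirrita autumnata,adult,24,2
Gratangen,Norway,68.72343,17.59460,Operophtera brumata,pupa,8,0
Abisko,Sweden,68.30850,18.51059,Epirrita autumnata,larva,59,1
Abisko,Sweden,68.30850,18.51059,Epirrita autumnata,pupa,8,0
Abisko,Sweden,68.30850,18.51059,Epirrita autumnata,adult,30,1
Abisko,Sweden,68.30850,18.51059,Operophtera brumata,pupa,3,0
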