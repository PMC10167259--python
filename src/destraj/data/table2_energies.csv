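des,ratio,pair,e_vdw,e_coul,e_total,s_printed,s_consistent
CCA,300:700,salt_water,-6.04,-12.5565,-18.5965,0.107255,True
CCA,300:700,salt_fas,-13.1565,-23.53296,-29.5729,0.107255,True
CCA,300:700,fas_water,-7.66,-249.4691,-257.1292,0.107255,True
CCA,500:500,salt_water,-5.3200,-139.9626,-145.2826,0.327813,True
CCA,500:500,salt_fas,-7.66,-116.40756,-124.0676,0.327813,True
CCA,500:500,fas_water,-10.2,-222.9875,-233.1876,0.327813,True
CCA,700:300,salt_water,-2.5,-116.04365,-118.5436,0.878032,False
CCA,700:300,salt_fas,-7.34,-173.7855,-181.1255,0.878032,False
CCA,700:300,fas_water,-16.26,-79.8365,-96.0965,0.878032,False
CLA,300:700,salt_water,-20.42,-94.5893,-115.0094,0.36219,True
CLA,300:700,salt_fas,0.3612,-137.4788,-137.1176,0.36219,True
CLA,300:700,fas_water,-7.84,-255.7198,-263.55988,0.36219,True
CLA,500:500,salt_water,-5.03,-174.7148,-179.7449,0.680039,True
CLA,500:500,salt_fas,1.06,-196.7638,-195.70383,0.680039,True
CLA,500:500,fas_water,-14.93,-93.1084,-108.0385,0.680039,True
CLA,700:300,salt_water,-3.6930,-193.606,-197.2936,0.843856,False
CLA,700:300,salt_fas,-5.23,-304.53,-309.7675,0.843856,False
CLA,700:300,fas_water,-16.77,-127.1285,-143.89866,0.843856,False
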