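family,genus,species_count,lineage_count,record_count,sources
Agamidae,Hypsilurus,1,2,73,25
Carphodactylidae,Carphodactylus,1,4,188,31
Carphodactylidae,Phyllurus,10,10,1259,28;32;33
Carphodactylidae,Saltuarius,5,6,339,31;34;35
Gekkonidae,Cyrtodactylus,5,5,71,29
Hylidae,Litoria,6,14,407,36
Myobatrachidae,Mixophyes,3,3,115,37
Scincidae,Carlia,2,5,1033,33;38
Scincidae,Eulamprus,3,6,1053,25;33
Scincidae,Glaphyromorphus,1,3,69,25
Scincidae,Gnypetoscincus,1,2,1351,25;31
Scincidae,Lampropholis,3,9,1084,12
Scincidae,Saproscincus,12,33,941,39;40
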