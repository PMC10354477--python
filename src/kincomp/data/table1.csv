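species,sex,composition,n_populations,n_units,n_datapoints,mean_unit_size,sd_unit_size,dispersal,breeding,litter
Cryptomys damarensis,F,related,3,15,15,6.2,2.8,philopatric,singular,polytocous
Ctenodactylus gundi,F,related,1,2,2,3.0,1.4,philopatric,plural,polytocous
Ctenodactylus gundi,M,related,1,2,2,2.5,0.7,philopatric,,
Marmota flaviventris,F,related,2,2,2,2.5,0.7,philopatric,plural,polytocous
Cynomys ludovicianus,F,related,1,3,3,2.0,,philopatric,plural,polytocous
Macaca mulatta,F,mix-related,1,5,9,53.1,23.8,philopatric,plural,monotocous
Macaca fascicularis,F,mix-related,1,1,1,13.0,,philopatric,plural,monotocous
Papio cynocephalus,F,mix-related,1,3,3,9.7,1.2,philopatric,plural,monotocous
Cercopithecus mitis,F,mix-related,1,3,3,15.2,5.2,philopatric,plural,monotocous
Pan troglodytes,F,mix-related,1,1,1,39.0,,disperse,plural,monotocous
Pan troglodytes,M,mix-related,1,1,1,12.0,,philopatric,,
Cebus capucinus,F,related,1,2,2,3.0,1.4,philopatric,plural,monotocous
Myotis bechsteinii,F,mix-related,1,4,4,22.0,9.0,philopatric,plural,monotocous
Eptesicus fuscus,F,mix-related,1,1,1,37.5,,philopatric,plural,monotocous
Artibeus jamaicensis,M,related,1,2,2,2.0,0.0,unclear,plural,monotocous
Orcinus orca,F,related,1,12,12,3.2,1.2,philopatric,plural,monotocous
Orcinus orca,M,related,1,5,5,2.4,0.5,philopatric,,
Canis lupus,F,related,2,3,4,2.0,0.0,philopatric,singular,polytocous
Canis lupus,M,related,1,1,1,3.0,,unclear,,
Cuon alpinus,F,related,1,1,1,2.0,,disperse,singular,polytocous
Vulpes vulpes,F,related,1,1,1,5.0,,philopatric,plural,polytocous
Crocuta crocuta,F,mix-related,1,1,1,21.0,,philopatric,plural,monotocous
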