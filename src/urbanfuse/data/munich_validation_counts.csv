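class,Sealed,Bushes and Shrubs,Grassland,Crops,Non- and sparsely vegetated,Water,Wetland,Needle-leaved trees,Broadleaved deciduous trees,Roads and Highways,Railways,Buildings
Sealed,54,0,1,0,2,0,0,0,1,6,1,2
Bushes and Shrubs,4,7,3,0,0,0,0,0,0,1,1,0
Grassland,2,0,56,0,0,0,2,0,2,2,0,1
Crops,0,2,1,45,0,0,0,0,0,0,0,0
Non- and sparsely vegetated,2,0,2,0,6,1,0,0,0,2,0,0
Water,0,0,0,0,0,9,4,0,0,0,0,0
Wetland,0,0,0,0,0,0,3,0,0,0,0,0
Needle-leaved trees,0,0,0,0,0,0,0,7,5,0,0,0
Broadleaved deciduous trees,3,1,4,0,1,0,1,3,101,7,0,0
Roads and Highways,1,0,0,0,0,0,0,0,0,57,0,1
Railways,0,0,1,0,0,0,0,0,2,0,9,0
Buildings,11,0,0,0,1,0,0,0,5,5,0,79
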