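name,height,weight,legs,danger,reproduction,fur,lungs,class
Jaguar,70,70,4,90,2,1,1,mammal
Donkey,100,200,4,10,2,1,1,mammal
Wild boar,70,180,4,20,2,1,1,mammal
Melontha,2.5,0.001,6,0,1,2,2,insect
Dragonfly,6,0.0003,6,0,1,2,2,insect
Wasp,1.5,0.00008,6,20,1,2,2,insect
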