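name,height,weight,legs,danger,reproduction,fur,lungs,class
Elephant,350,6000,4,60,2,2,1,mammal
Tiger,100,100,4,100,2,1,1,mammal
Lion,120,175,4,100,2,1,1,mammal
Dog,70,30,4,20,2,1,1,mammal
Rabbit,40,2,4,0,2,1,1,mammal
Bear,200,500,4,60,2,1,1,mammal
Cow,120,500,4,20,2,1,1,mammal
Deer,70,20,4,0,2,1,1,mammal
Cat,30,4,4,5,2,1,1,mammal
Beaver,60,25,4,5,2,1,1,mammal
Giraffe,500,1200,4,40,2,1,1,mammal
Ape,70,40,4,30,2,1,1,mammal
Horse,120,250,4,10,2,1,1,mammal
Camel,125,400,4,10,2,1,1,mammal
Goat,70,60,4,5,2,1,1,mammal
Sheep,60,20,4,5,2,1,1,mammal
Pig,60,200,4,5,2,2,1,mammal
Hamster,5,0.2,4,0,2,1,1,mammal
Dolphine,200,60,0,10,2,2,1,mammal
Raccoon,50,15,4,5,2,1,1,mammal
Red Pander,30,5,4,5,2,1,1,mammal
Ant,0.1,0.00001,6,1,1,2,2,insect
Bee,1,0.0001,6,5,1,2,2,insect
Cockroach,5,0.005,6,0,1,2,2,insect
Goliathus,8,5,6,0,1,2,2,insect
Giant weta,10,0.035,6,0,1,2,2,insect
Heteropteryx,15,0.05,6,0,1,2,2,insect
Cane toad,15,1,4,0,1,2,1,amphibian
Fire Salamander,17,0.035,4,0,1,2,1,amphibian
Frog,4,0.01,4,0,1,2,1,amphibian
Olm,20,0.02,4,0,1,2,1,amphibian
Tree Frog,4,0.005,4,0,1,2,1,amphibian
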