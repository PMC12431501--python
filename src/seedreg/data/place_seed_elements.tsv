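name	consensus	description
ABREZMRAB28	CCACGTGG	ABA and water-stress response element
O2F2BE2S1	GCCACCTCAT	Seed-specific expression element
RYREPEATGMGY2	CATGCAT	Seed-specific expression element
RYREPEATVFLEB4	CATGCATG	ABA response and seed storage protein expression element
AMYBOX1	TAACARA	Seed-specific expression element
AUXRETGA2GMGH3	TGACGTGGC	Auxin-responsive element
GARE1OSREP1	TAACAGA	Seed-specific expression and GA-responsive element
-300ELEMENT	TGHAAARK	Seed storage protein expression element
SEF4MOTIFGM7S	RTTTTTR	Seed storage protein expression element
TATABOX1	CTATAAATAC	TATA box-like and seed-specific expression element
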