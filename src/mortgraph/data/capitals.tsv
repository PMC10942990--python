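# code	name	capital_lat	capital_lon
AUT	Austria	48.2082	16.3738
BEL	Belgium	50.8503	4.3517
CHE	Switzerland	46.9480	7.4474
CZE	Czechia	50.0755	14.4378
DNK	Denmark	55.6761	12.5683
ESP	Spain	40.4168	-3.7038
FIN	Finland	60.1699	24.9384
FRATNP	France	48.8566	2.3522
GBR_NP	United Kingdom	51.5074	-0.1278
HUN	Hungary	47.4979	19.0402
ITA	Italy	41.9028	12.4964
NLD	Netherlands	52.3676	4.9041
NOR	Norway	59.9139	10.7522
PRT	Portugal	38.7223	-9.1393
SVK	Slovakia	48.1486	17.1077
SWE	Sweden	59.3293	18.0686
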