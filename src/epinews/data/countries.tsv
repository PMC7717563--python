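Afghanistan	Afghanistan
Algeria	Algeria
Angola	Angola
Argentina	Argentina
Australia	Australia
Bangladesh	Bangladesh
Belgium	Belgium
Benin	Benin
Bolivia	Bolivia
Brazil	Brazil
Burkina Faso	Burkina Faso
Burundi	Burundi
Cambodia	Cambodia
Cameroon	Cameroon
Canada	Canada
Central African Republic	Central African Republic
Chad	Chad
Chile	Chile
China	China
Colombia	Colombia
Democratic Republic of the Congo	Democratic Republic of the Congo
DR Congo	Democratic Republic of the Congo
DRC	Democratic Republic of the Congo
Congo	Republic of the Congo
Ecuador	Ecuador
Egypt	Egypt
Ethiopia	Ethiopia
France	France
Germany	Germany
Ghana	Ghana
Greece	Greece
Guinea	Guinea
Haiti	Haiti
India	India
Indonesia	Indonesia
Iran	Iran
Iraq	Iraq
Italy	Italy
Japan	Japan
Kenya	Kenya
Liberia	Liberia
Madagascar	Madagascar
Malawi	Malawi
Malaysia	Malaysia
Mali	Mali
Mexico	Mexico
Mozambique	Mozambique
Myanmar	Myanmar
Namibia	Namibia
Nepal	Nepal
Niger	Niger
Nigeria	Nigeria
Pakistan	Pakistan
Peru	Peru
Philippines	Philippines
Russia	Russia
Rwanda	Rwanda
Saudi Arabia	Saudi Arabia
Senegal	Senegal
Sierra Leone	Sierra Leone
Somalia	Somalia
South Africa	South Africa
South Sudan	South Sudan
Spain	Spain
Sudan	Sudan
Tanzania	Tanzania
Thailand	Thailand
Togo	Togo
Uganda	Uganda
Ukraine	Ukraine
United Kingdom	United Kingdom
United States	United States
USA	United States
Venezuela	Venezuela
Vietnam	Vietnam
Yemen	Yemen
Zambia	Zambia
Zimbabwe	Zimbabwe
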