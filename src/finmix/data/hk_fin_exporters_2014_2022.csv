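nation,mean_annual_kg,range_state_count,fao_rfmo_catch,seizure_implicated,cites_reporting
Spain,725105.67,5,Yes,No,No
Singapore,605283,2,No,No,Yes
Senegal,315602.67,4,No,Yes,Yes
Indonesia,298621.33,3,No,Yes,Yes
Taiwan Province of China,257287,4,No,No,No
Peru,231270.89,4,Yes,Yes,Yes
Mexico,144508.44,4,No,Yes,Yes
Yemen,137076.33,4,No,Yes,Yes
United Arab Emirates,97553.11,3,No,Yes,No
Argentina,85395.63,3,No,No,No
United States,83371.67,5,Yes,No,Yes
Oman,71103.56,4,Yes,No,Yes
South Africa,68709,5,No,No,No
Ecuador,66424.86,4,Yes,Yes,No
Sri Lanka,60168.11,4,Yes,Yes,Yes
The Mainland of China,55632,4,Yes,Yes,No
Japan,50087.56,4,Yes,No,No
Costa Rica,48511.67,4,No,Yes,Yes
Uruguay,35227.57,5,No,No,No
India,34888.75,4,No,Yes,Yes
Philippines,30270.63,4,No,Yes,No
South Korea,28031.13,3,No,No,Yes
Ghana,27104.22,4,No,Yes,No
Brazil,26552.22,5,No,Yes,No
Trinidad & Tobago,24328.5,4,No,No,No
New Zealand,23827.5,3,Yes,No,No
France,22245.13,5,No,No,No
Togo,19843.75,3,No,No,No
Pakistan,15342.11,4,No,Yes,No
Morocco,14602.78,5,Yes,Yes,No
El Salvador,14326.88,3,No,No,Yes
Guinea,12381.38,4,Yes,Yes,No
Somalia,12343.38,4,No,Yes,No
Chile,12190.78,3,No,No,No
Bangladesh,11658,3,No,No,No
Namibia,10725.33,3,No,No,No
Guyana,10206.38,3,No,Yes,No
Guatemala,9935.33,3,No,Yes,No
Australia,9710.22,5,No,No,Yes
Malaysia,9642.78,2,No,No,No
Madagascar,8633.11,4,No,Yes,No
Kenya,8360.89,3,Yes,Yes,Yes
Thailand,8081.67,3,No,No,No
Panama,7663.38,4,No,Yes,No
Mauritania,6803,4,Yes,No,No
Mozambique,6719,3,No,No,No
Papua New Guinea,6587.78,3,No,No,Yes
Tunisia,5025.13,4,No,No,No
Sierra Leone,4829.11,3,No,No,No
Colombia,4629.17,4,No,Yes,Yes
Canada,3531.67,2,No,No,No
Nicaragua,3481.11,3,No,Yes,No
Angola,3429.17,3,No,No,No
Mauritius,3347.8,3,No,No,No
Venezuela,3287.5,3,Yes,Yes,No
Saudi Arabia,3233.38,4,No,No,No
Congo,2842.33,3,No,Yes,No
Vietnam,2652,4,No,No,No
Solomon Is,2462.5,3,No,No,No
Seychelles,2256.22,4,Yes,Yes,No
Germany,2131.75,2,No,No,No
Democratic Republic of the Congo,2107.25,3,No,Yes,No
Egypt,2002.38,5,No,Yes,No
Cuba,1607.83,4,No,No,No
Norway,1357.33,2,No,No,No
Turkey,1307.86,0,No,No,No
Fiji,1307,3,Yes,No,No
Iran,1106,3,Yes,No,No
Cote D'Ivoire,974,4,No,No,No
Nigeria,880.43,2,No,No,No
Ethiopia,865.83,0,No,No,No
Bahrain,851.89,3,No,No,No
Liberia,524.83,4,Yes,No,No
Tanzania,441.71,3,No,Yes,No
Aruba,384,3,No,No,No
Belize,307.4,3,No,No,No
Mali,293,0,No,No,No
Macau,226.2,4,No,No,No
Sweden,202,2,No,No,No
Maldives,189.43,3,No,No,No
Uganda,137.4,0,No,No,No
Libya,114,4,No,No,No
Zimbabwe,90,0,No,No,No
Zambia,83.33,0,No,No,No
Kuwait,60.2,3,No,No,No
Cameroon,59.75,4,No,No,No
Vanuatu,58,1,No,No,No
Northern Mariana Islands,46.5,1,No,No,No
Sudan,38.6,3,No,No,No
Dominican Republic,29.4,4,No,No,No
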