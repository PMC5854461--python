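country,mcpr,mcpr_lower,mcpr_upper,unmet_modern,unmet_modern_lower,unmet_modern_upper,demand_satisfied,demand_satisfied_lower,demand_satisfied_upper
Afghanistan,20.9,16.0,27.1,27.9,22.9,33.4,42.7,34.7,51.7
Bangladesh,56.4,46.1,65.7,19.2,13.7,26.3,74.5,64.3,82.5
Benin,13.0,8.0,19.6,36.1,28.6,44.1,26.5,17.4,36.8
Bhutan,64.6,48.1,78.9,12.7,6.0,23.2,83.4,68.0,92.8
Bolivia,44.1,26.7,60.4,36.7,23.2,53.5,54.5,33.5,71.9
Burkina Faso,24.7,21.1,28.8,27.2,21.6,33.6,47.6,40.9,55.1
Burundi,25.2,20.4,30.7,33.1,28.6,37.8,43.2,36.4,50.5
Cambodia,42.8,31.8,53.4,28.8,21.0,39.9,59.8,45.4,71.2
Cameroon,21.8,13.2,29.7,33.2,25.6,42.1,39.6,26.0,50.8
Central African Republic,14.5,6.8,27.4,30.0,20.6,41.5,32.4,17.8,51.1
Chad,4.3,2.7,6.8,22.7,18.0,28.2,16.0,10.4,23.6
Comoros,18.7,11.1,29.4,35.9,28.6,44.0,34.1,22.1,48.0
Congo (Brazzaville),23.9,14.5,35.6,37.9,28.3,49.1,38.5,24.3,54.0
Côte d'Ivoire,15.8,12.1,20.0,29.0,22.4,36.6,35.3,27.6,43.6
Democratic Republic of the Congo,10.0,5.8,16.2,39.9,32.1,48.4,20.0,12.1,30.3
Djibouti,24.3,15.1,36.1,30.0,19.6,42.1,44.7,30.4,61.1
Egypt,59.7,49.3,69.5,12.9,8.4,18.3,82.2,73.3,89.1
Eritrea,9.7,5.2,18.2,30.4,21.7,40.6,24.4,13.8,38.8
Ethiopia,37.5,31.6,43.6,23.7,19.9,27.9,61.2,54.3,67.8
Gambia,9.8,6.0,15.3,26.7,20.6,33.9,26.8,17.6,38.2
Ghana,27.1,22.0,32.9,34.0,28.7,39.7,44.3,37.3,52.0
Guinea,6.2,3.4,10.8,25.6,19.5,32.8,19.5,11.5,30.4
Guinea-Bissau,16.3,9.2,26.6,23.2,15.6,32.6,41.2,26.4,57.4
Haiti,35.4,24.2,48.4,35.5,27.0,43.9,49.8,36.6,63.6
Honduras,65.4,52.8,75.8,18.6,11.6,28.4,77.8,65.4,86.6
India,52.8,44.8,60.7,18.9,14.7,24.3,73.7,65.8,80.0
Indonesia,59.4,51.6,67.0,13.7,9.7,18.7,81.2,74.1,87.1
Iraq,43.6,27.9,59.1,27.4,16.8,41.0,61.2,41.6,77.3
Kenya,62.3,54.0,69.6,16.8,12.4,22.3,78.8,71.2,84.7
Kyrgyzstan,39.1,27.9,51.3,20.3,14.8,26.5,65.7,53.2,76.7
Laos,49.4,35.7,62.2,23.2,15.6,32.6,67.9,53.3,79.8
Lesotho,60.9,50.6,70.4,17.8,12.1,24.7,77.4,67.6,85.1
Liberia,23.6,16.0,30.1,31.5,25.5,38.1,42.7,32.2,51.6
Madagascar,39.5,27.4,52.8,24.9,17.4,33.5,61.3,46.9,74.2
Malawi,58.5,50.6,66.1,19.2,14.6,24.3,75.3,67.9,81.8
Mali,13.5,8.7,20.1,26.5,20.8,33.1,33.7,23.6,44.9
Mauritania,16.0,9.9,24.4,32.6,24.4,41.8,32.9,22.0,46.0
Mongolia,53.2,39.8,65.6,20.0,12.7,29.7,72.7,58.5,83.3
Mozambique,31.4,19.7,38.1,24.9,20.2,30.6,55.7,41.3,63.9
Myanmar,52.2,44.9,59.2,17.0,13.2,21.3,75.4,68.4,81.4
Nepal,50.8,39.6,61.9,25.9,18.2,34.3,66.2,54.2,77.1
Nicaragua,77.4,67.3,85.0,10.2,6.0,16.6,88.4,80.4,93.4
Niger,14.7,10.9,19.2,20.9,16.2,26.6,41.3,32.9,50.1
Nigeria,13.1,9.8,17.3,25.3,20.6,30.7,34.1,26.6,42.4
North Korea,64.3,48.7,77.6,16.5,8.9,27.6,79.6,64.6,89.6
Pakistan,30.6,24.4,38.0,29.7,23.3,37.3,50.8,41.6,60.1
Palestine,47.4,32.8,61.6,25.0,15.7,37.5,65.5,48.1,79.2
Papua New Guinea,28.7,14.8,46.4,32.1,21.6,44.6,46.9,28.0,66.2
Philippines,41.4,30.0,53.4,31.9,23.5,42.1,56.4,42.4,69.1
Rwanda,50.2,41.7,58.5,23.3,17.9,29.3,68.3,59.3,76.2
São Tomé and Príncipe,46.8,33.9,60.0,31.2,21.5,41.2,59.9,45.6,73.4
Senegal,21.7,15.6,29.2,26.9,22.5,31.6,44.6,35.5,54.3
Sierra Leone,19.5,13.1,26.2,27.1,21.3,33.4,41.8,31.0,51.8
Solomon Islands,31.2,17.1,48.4,27.4,17.9,38.9,52.7,34.3,71.1
Somalia,2.6,0.7,7.7,31.4,19.8,45.5,7.8,2.3,20.1
South Sudan,3.6,1.7,8.0,30.6,19.9,43.2,10.7,4.9,22.0
Sri Lanka,58.5,38.5,74.7,21.7,11.1,39.3,72.8,50.5,86.8
Sudan,13.0,7.6,21.2,29.4,21.2,39.4,30.6,19.3,44.5
Tajikistan,30.0,19.6,42.8,24.9,18.7,32.0,54.4,40.8,67.8
Timor-Leste,25.2,20.1,31.1,27.4,22.9,32.1,47.9,40.2,55.7
Togo,20.9,14.8,26.2,35.3,29.3,41.7,37.2,28.3,45.1
Uganda,34.3,28.8,40.1,33.2,28.7,38.0,50.7,44.1,57.6
Tanzania,34.9,27.4,42.3,27.8,22.8,33.5,55.6,46.2,64.1
Uzbekistan,65.7,47.0,80.8,12.6,5.9,22.9,83.8,68.1,93.0
Vietnam,66.3,55.6,75.5,17.4,11.0,26.6,79.2,68.0,87.1
Yemen,33.6,23.8,45.4,31.8,24.5,39.3,51.3,39.2,64.0
Zambia,48.2,37.2,59.7,23.6,17.0,30.8,67.1,55.5,77.5
Zimbabwe,66.3,56.1,73.0,11.9,8.0,18.0,84.7,76.2,89.9
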