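country,post_2012_data,mcpr_change,mcpr_change_lower,mcpr_change_upper,unmet_modern_change,unmet_modern_change_lower,unmet_modern_change_upper,demand_satisfied_change,demand_satisfied_change_lower,demand_satisfied_change_upper,users_change_millions,users_change_lower,users_change_upper
Afghanistan,1,4.5,-1.3,11.1,-0.3,-6.6,5.8,5.9,-3.6,15.7,0.37,0.08,0.71
Bangladesh,1,2.8,-7.9,13.1,-1.4,-7.6,5.8,2.4,-8.2,11.3,2.11,-1.76,5.82
Benin,1,4.6,-0.4,11.1,-1.4,-8.3,5.8,8.2,-0.7,18.2,0.1,0.01,0.21
Bhutan,0,3.7,-8.2,14.6,-1.6,-7.4,5.0,2.6,-7.4,11.0,0.02,0.0,0.03
Bolivia,0,4.3,-8.6,17.3,-3.9,-15.2,7.8,5.1,-9.8,19.3,0.11,-0.08,0.3
Burkina Faso,1,7.5,2.0,13.0,-0.2,-5.7,5.4,9.0,0.3,17.8,0.32,0.15,0.49
Burundi,1,-1.8,-7.3,4.2,1.0,-4.3,6.4,-2.5,-10.3,5.2,0.04,-0.05,0.13
Cambodia,1,5.3,-6.7,17.0,-2.3,-10.7,7.9,5.0,-9.2,17.8,0.22,-0.1,0.54
Cameroon,1,6.1,-2.4,14.3,-0.6,-7.8,7.0,7.9,-5.0,19.6,0.29,-0.02,0.59
Central African Republic,0,3.0,-2.9,12.5,-0.2,-6.9,6.9,5.0,-6.0,18.1,0.04,-0.02,0.14
Chad,1,1.5,-0.2,3.9,0.6,-5.0,6.4,4.8,-1.3,12.2,0.05,0.01,0.11
Comoros,0,3.9,-3.2,14.0,-1.1,-7.8,6.1,5.6,-5.4,18.5,0.01,0.0,0.02
Congo (Brazzaville),1,3.5,-5.7,14.9,-3.2,-12.2,6.3,5.4,-8.1,20.2,0.04,-0.02,0.11
Côte d'Ivoire,1,3.2,-0.9,7.8,0.4,-5.5,7.3,4.8,-3.2,12.9,0.1,-0.04,0.26
Democratic Republic of the Congo,1,2.3,-2.5,8.9,-0.4,-8.1,7.9,4.2,-4.8,14.5,0.43,-0.19,1.27
Djibouti,0,5.1,-3.5,16.2,-1.2,-8.4,5.6,6.5,-6.1,19.6,0.01,0.0,0.02
Egypt,1,0.9,-11.2,12.6,-0.1,-5.7,5.7,0.4,-9.4,9.1,1.03,-0.96,2.95
Eritrea,0,2.0,-1.8,8.7,0.3,-6.3,7.3,3.8,-4.9,14.8,0.02,-0.01,0.08
Ethiopia,1,6.9,-0.7,14.3,-3.3,-8.1,1.7,8.1,-0.7,16.6,1.66,0.58,2.76
Gambia,1,0.7,-3.3,6.3,0.3,-5.7,6.5,1.3,-8.2,12.1,0.01,-0.01,0.02
Ghana,1,5.0,-2.0,12.4,-3.3,-9.7,3.1,7.1,-2.1,16.7,0.28,0.0,0.58
Guinea,0,1.3,-1.4,5.7,0.8,-4.9,7.4,3.1,-4.4,13.0,0.04,-0.02,0.13
Guinea-Bissau,1,3.1,-3.1,11.6,0.8,-4.8,6.5,4.1,-7.5,16.5,0.01,0.0,0.03
Haiti,0,4.3,-6.4,16.4,-3.2,-11.1,4.6,5.1,-7.1,18.1,0.13,-0.06,0.34
Honduras,0,1.5,-10.0,11.3,-1.2,-7.8,7.6,1.5,-9.7,9.8,0.11,-0.05,0.23
India,1,0.1,-8.6,9.0,-0.8,-5.8,4.8,0.8,-7.5,8.3,6.39,-15.53,29.01
Indonesia,1,-1.1,-9.1,6.8,0.6,-3.4,5.4,-0.9,-7.9,5.0,0.43,-3.65,4.38
Iraq,0,3.4,-8.8,15.6,-1.2,-9.8,8.5,2.9,-11.6,15.5,0.49,-0.22,1.17
Kenya,1,12.7,2.3,22.5,-7.8,-14.1,-1.1,11.9,2.1,20.9,1.26,0.58,1.89
Kyrgyzstan,1,4.1,-6.8,16.1,-0.6,-5.9,5.1,3.1,-9.1,14.0,0.06,-0.06,0.18
Laos,0,5.4,-6.7,17.0,-2.7,-9.6,5.3,5.0,-7.6,15.5,0.15,-0.02,0.31
Lesotho,1,7.4,-3.9,18.3,-4.3,-11.0,3.3,6.6,-4.2,16.1,0.03,0.0,0.05
Liberia,1,6.5,-1.7,13.9,-1.7,-8.0,5.0,8.9,-2.6,18.9,0.05,0.0,0.1
Madagascar,0,6.2,-5.1,18.5,-2.3,-9.2,5.1,6.2,-7.0,18.5,0.45,-0.03,0.98
Malawi,1,9.7,-0.5,19.6,-6.1,-12.6,0.4,9.5,-0.4,18.9,0.48,0.21,0.73
Mali,1,3.6,-1.3,10.0,-0.2,-6.0,5.6,6.7,-3.2,17.6,0.16,0.0,0.37
Mauritania,1,4.3,-1.5,11.8,-0.4,-7.2,6.3,6.7,-2.9,17.5,0.03,0.0,0.08
Mongolia,1,2.5,-9.5,14.0,-1.0,-7.7,6.6,2.0,-9.9,11.8,0.02,-0.04,0.08
Mozambique,1,15.7,4.6,23.0,-2.5,-7.9,3.3,19.2,5.5,28.7,0.77,0.28,1.09
Myanmar,1,5.9,-4.9,16.5,-2.5,-8.4,3.4,5.2,-5.0,15.5,0.61,-0.32,1.53
Nepal,1,5.4,-5.7,16.3,-4.4,-11.9,3.5,6.2,-5.5,17.0,0.62,-0.06,1.28
Nicaragua,0,0.7,-8.7,7.8,-0.4,-4.4,5.2,0.5,-6.6,5.2,0.06,-0.04,0.13
Niger,1,2.6,-1.4,7.3,2.2,-2.1,7.4,1.9,-6.6,10.9,0.2,0.04,0.4
Nigeria,1,2.7,-0.9,7.1,2.8,-2.3,8.2,2.4,-5.5,11.0,1.11,0.06,2.42
North Korea,0,1.1,-10.1,11.1,-0.7,-6.9,6.7,1.0,-9.3,9.2,0.02,-0.47,0.45
Pakistan,1,5.2,-2.2,13.1,-0.9,-7.3,6.1,5.4,-4.8,15.5,2.45,0.16,4.95
Palestine,1,2.5,-9.3,14.9,-0.8,-8.9,8.3,2.0,-11.3,14.2,0.05,-0.02,0.12
Papua New Guinea,0,1.9,-8.0,13.7,-1.0,-8.8,6.3,2.4,-10.1,15.7,0.06,-0.07,0.22
Philippines,1,4.1,-7.7,16.5,-2.4,-11.1,7.5,4.3,-9.8,17.2,1.12,-0.77,3.12
Rwanda,1,4.5,-5.5,14.3,-3.6,-10.0,3.2,5.4,-5.1,15.0,0.14,-0.01,0.29
São Tomé and Príncipe,1,6.0,-6.0,17.6,-5.0,-13.5,4.0,7.1,-5.8,18.9,0.0,0.0,0.01
Senegal,1,6.4,0.0,14.3,-3.0,-8.2,2.4,10.8,0.9,21.2,0.2,0.05,0.4
Sierra Leone,1,6.4,-0.4,13.5,-0.4,-6.3,5.8,9.5,-1.7,20.3,0.08,0.01,0.15
Solomon Islands,0,1.8,-8.5,13.6,-0.4,-7.4,6.4,1.7,-11.1,14.5,0.0,-0.01,0.02
Somalia,0,0.7,-0.4,3.9,0.2,-6.9,7.5,1.8,-1.5,9.2,0.01,0.0,0.06
South Sudan,0,0.8,-0.7,4.1,0.4,-6.5,7.4,2.2,-2.3,10.0,0.03,0.0,0.1
Sri Lanka,0,1.9,-11.0,14.3,-1.1,-10.7,9.4,1.6,-11.9,14.0,0.05,-0.39,0.48
Sudan,1,2.3,-2.9,9.3,0.1,-6.5,6.7,3.9,-6.2,14.7,0.2,-0.11,0.65
Tajikistan,0,3.5,-6.6,15.5,-0.5,-6.2,5.5,3.4,-9.5,15.8,0.09,-0.07,0.28
Timor-Leste,1,3.1,-4.1,10.2,-1.7,-7.1,3.7,4.7,-5.0,14.5,0.0,-0.01,0.01
Togo,1,4.6,-2.2,11.1,-1.9,-8.2,4.9,6.8,-3.1,15.9,0.08,0.0,0.16
Uganda,1,7.3,0.0,14.5,-4.1,-9.6,1.5,8.8,0.0,17.5,0.66,0.27,1.04
Tanzania,1,5.4,-3.8,14.6,-2.3,-8.2,3.7,6.2,-4.8,16.6,0.72,0.03,1.42
Uzbekistan,0,1.2,-10.3,11.6,-0.4,-5.7,5.7,0.6,-8.5,8.3,0.3,-0.35,0.89
Vietnam,1,-0.2,-11.2,9.3,0.4,-6.1,9.4,-0.5,-11.4,7.7,0.59,-1.49,2.37
Yemen,1,5.4,-5.4,17.3,-2.2,-9.5,5.3,5.8,-7.0,19.2,0.4,-0.05,0.9
Zambia,1,6.3,-6.0,18.4,-3.9,-11.1,3.8,6.6,-5.8,18.3,0.29,0.01,0.56
Zimbabwe,1,5.6,-4.3,14.1,-2.7,-7.2,3.0,4.2,-4.2,10.8,0.35,0.08,0.56
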