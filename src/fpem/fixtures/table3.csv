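country,eval_year,gap_pp,gap_users_millions,attainment_prob_pct,fp2020_commitment
Mozambique,2016,14.1,0.61,0,1
Kenya,2015,14.3,0.92,2,1
Sierra Leone,2016,7.7,0.08,3,1
Chad,2014,1.4,0.03,7,0
Liberia,2016,7.7,0.05,10,1
Lesotho,2014,7.5,0.02,11,0
Malawi,2015,8.4,0.21,11,1
Senegal,2015,3.2,0.08,15,1
Zimbabwe,2016,5.2,0.13,18,1
Burkina Faso,2017,4.6,0.15,19,1
São Tomé and Príncipe,2014,5.7,0.0,22,0
Benin,2015,1.5,0.03,25,1
Mali,2015,1.5,0.05,26,1
Mauritania,2015,1.8,0.01,32,1
Zambia,2013,3.4,0.07,32,1
Cameroon,2016,1.5,0.05,36,1
Ethiopia,2016,2.1,0.31,38,1
Kyrgyzstan,2014,1.3,0.01,38,0
Palestine,2014,1.2,0.01,43,0
Myanmar,2016,1.1,0.1,44,1
Guinea-Bissau,2014,0.5,0.0,45,0
Togo,2016,0.3,0.0,45,1
Afghanistan,2016,0.3,0.02,47,1
Philippines,2013,0.3,0.05,47,1
Ghana,2016,0.2,0.01,49,1
Uganda,2016,0.1,0.01,49,1
Sudan,2014,0.0,0.0,50,0
Nigeria,2017,-0.2,-0.05,51,1
Nepal,2015,-0.4,-0.02,53,1
Pakistan,2016,-0.1,-0.02,53,1
Niger,2016,-0.4,-0.01,54,1
Côte d'Ivoire,2016,-0.6,-0.02,56,1
Tanzania,2016,-1.4,-0.11,57,1
Cambodia,2014,-1.2,-0.03,58,0
India,2016,-1.5,-3.69,58,1
Yemen,2013,-1.7,-0.07,58,0
Bangladesh,2014,-1.0,-0.37,59,1
Vietnam,2014,-0.7,-0.12,60,1
Mongolia,2013,-1.9,-0.01,63,0
Rwanda,2016,-2.3,-0.03,63,1
Timor-Leste,2016,-2.9,0.0,67,0
Congo (Brazzaville),2014,-2.0,-0.01,68,0
Egypt,2014,-4.0,-0.64,72,0
Democratic Republic of the Congo,2013,-1.6,-0.19,74,1
Indonesia,2015,-3.2,-1.59,74,1
Burundi,2016,-9.5,-0.15,96,1
Gambia,2013,-6.2,-0.02,97,0
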