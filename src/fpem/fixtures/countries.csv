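country_code,name,subregion,region,fp2020_commitment
AFG,Afghanistan,Southern Asia,Asia,1
BDI,Burundi,Eastern Africa,Africa,1
BEN,Benin,Western Africa,Africa,1
BFA,Burkina Faso,Western Africa,Africa,1
BGD,Bangladesh,Southern Asia,Asia,1
BOL,Bolivia,South America,Latin America and the Caribbean,
BTN,Bhutan,Southern Asia,Asia,
CAF,Central African Republic,Middle Africa,Africa,
CIV,Côte d'Ivoire,Western Africa,Africa,1
CMR,Cameroon,Middle Africa,Africa,1
COD,Democratic Republic of the Congo,Middle Africa,Africa,1
COG,Congo (Brazzaville),Middle Africa,Africa,0
COM,Comoros,Eastern Africa,Africa,
DJI,Djibouti,Eastern Africa,Africa,
EGY,Egypt,Northern Africa,Africa,0
ERI,Eritrea,Eastern Africa,Africa,
ETH,Ethiopia,Eastern Africa,Africa,1
GHA,Ghana,Western Africa,Africa,1
GIN,Guinea,Western Africa,Africa,
GMB,Gambia,Western Africa,Africa,0
GNB,Guinea-Bissau,Western Africa,Africa,0
HND,Honduras,Central America,Latin America and the Caribbean,
HTI,Haiti,Caribbean,Latin America and the Caribbean,
IDN,Indonesia,South-eastern Asia,Asia,1
IND,India,Southern Asia,Asia,1
IRQ,Iraq,Western Asia,Asia,
KEN,Kenya,Eastern Africa,Africa,1
KGZ,Kyrgyzstan,Central Asia,Asia,0
KHM,Cambodia,South-eastern Asia,Asia,0
LAO,Laos,South-eastern Asia,Asia,
LBR,Liberia,Western Africa,Africa,1
LKA,Sri Lanka,Southern Asia,Asia,
LSO,Lesotho,Southern Africa,Africa,0
MDG,Madagascar,Eastern Africa,Africa,
MLI,Mali,Western Africa,Africa,1
MMR,Myanmar,South-eastern Asia,Asia,1
MNG,Mongolia,Eastern Asia,Asia,0
MOZ,Mozambique,Eastern Africa,Africa,1
MRT,Mauritania,Western Africa,Africa,1
MWI,Malawi,Eastern Africa,Africa,1
NER,Niger,Western Africa,Africa,1
NGA,Nigeria,Western Africa,Africa,1
NIC,Nicaragua,Central America,Latin America and the Caribbean,
NPL,Nepal,Southern Asia,Asia,1
PAK,Pakistan,Southern Asia,Asia,1
PHL,Philippines,South-eastern Asia,Asia,1
PNG,Papua New Guinea,Melanesia,Oceania,
PRK,North Korea,Eastern Asia,Asia,
PSE,Palestine,Western Asia,Asia,0
RWA,Rwanda,Eastern Africa,Africa,1
SDN,Sudan,Northern Africa,Africa,0
SEN,Senegal,Western Africa,Africa,1
SLB,Solomon Islands,Melanesia,Oceania,
SLE,Sierra Leone,Western Africa,Africa,1
SOM,Somalia,Eastern Africa,Africa,
SSD,South Sudan,Eastern Africa,Africa,
STP,São Tomé and Príncipe,Middle Africa,Africa,0
TCD,Chad,Middle Africa,Africa,0
TGO,Togo,Western Africa,Africa,1
TJK,Tajikistan,Central Asia,Asia,
TLS,Timor-Leste,South-eastern Asia,Asia,0
TZA,Tanzania,Eastern Africa,Africa,1
UGA,Uganda,Eastern Africa,Africa,1
UZB,Uzbekistan,Central Asia,Asia,
VNM,Vietnam,South-eastern Asia,Asia,1
YEM,Yemen,Western Asia,Asia,0
ZMB,Zambia,Eastern Africa,Africa,1
ZWE,Zimbabwe,Eastern Africa,Africa,1
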