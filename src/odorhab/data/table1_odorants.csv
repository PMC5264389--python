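cas,abbrev,name,asa,c_chain,logp,db_bonds,conformers,mw,vp,ofamily,cfamily
55066-48-3,Mef,MEFROSOL,42.20,5,2.7,3,17,178,0.0004,Floral,ALCO
676532-44-8,Syl,SYLKOLIDE,86.71,5,4.4,2,144,268,0.0046,Musky,ETHER
81782-77-6,Und,UNDECAVERTOL,63.17,10,3.9,1,64,170,0.0110,Green,ALCO
65113-99-7,Sand,SANDALORE,38.60,5,4.73,1,106,210,0.0010,Woody,ALCO
488-10-8,Jas,JASMONE,16.19,5,2.8,3,6,164,0.0133,Floral,KETO
97-54-1,Iso,ISOEUGENOL,8.34,3,2.1,4,23,164,0.0040,Spicy,ETHER
16510-27-3,Tos,TOSCANOL,11.09,3,3.8,3,1,162,0.0113,Agrestic,ALCO
54440-17-4,Saf,SAFRALEINE,0.00,1,2.9,4,7,174,0.0120,Spicy,KETO
928-96-1,Hex,HEXENOL Cis-3,20.20,6,1,1,37,100,0.5333,Green,ALCO
80-54-6,Lil,LILIAL,14.19,3,4.2,4,15,204,0.0040,Floral,ALDE
67801-20-1,Eba,EBANOL,24.20,5,4.2,2,39,208,0.0054,Woody,ALCO
873888-84-7,Kar,KARMAFLOR,60.71,6,5,5,83,234,0.0010,Floral,ESTER
28940-11-6,Cal,CALONE,4.89,1,1.2,4,70,178,0.0133,Aldehydic,ETHER
95962-14-4,Nec,NECTARYL,39.30,1,4.8,2,4,220,0.0001,Fruity,KETO
28645-51-4,Ambt,AMBRETTOLIDE,44.47,0,6,2,78,252,0.0003,Musky,LACTONE
916887-53-1,Pet,PETALIA,9.69,1,3.45,4,46,211,0.0002,Floral,NITRILE
6790-58-5,Ambx,AMBROFIX,0.00,1,6,0,11,236,0.0013,Woody,ETHER
871465-49-5,Cas,CASSYRANE,11.67,3,4.45,1,21,182,0.1040,Fruity,ETHER
79-69-6,Iro,IRONE ALPHA,14.44,4,3.8,3,3,206,0.0053,Floral,KETO
54464-57-2,IsoE,ISO E SUPER,9.59,2,5.7,2,15,234,0.0027,Woody,KETO
97-53-0,Eug,EUGENOL,7.54,3,2,4,27,164,0.0112,Spicy,ETHER
08.11.4940,Eth,ETHYL MALTOL,6.70,2,1.69,3,22,140,0.1333,Sweet,ETHER
125109-85-5,Flo,FLORHYDRAL,18.20,3,3.1,4,5,190,0.0065,Aldehydic,ALDE
32669-00-4,Tan,TANAISONE,13.93,2,3,2,34,152,0.0970,Agrestic,KETO
1222-05-5,Gal,GALAXOLIDE,3.28,1,5.9,3,18,258,0.0133,Musky,ETHER
18127-01-0,Bou,BOURGEONAL,14.99,1,3.2,4,40,190,0.4037,Floral,ALDE
57378-68-4,Dam,DAMASCONE DELTA,15.76,4,4.2,3,5,192,0.0267,Floral,KETO
357650-26-1,Pom,POMAROSE,14.50,8,3.3,4,10,166,0.1410,Fruity,KETO
39255-32-8,Man,MANZANATE,37.91,4,2.65,1,17,144,1.9997,Fruity,ESTER
61792-11-8,Lem,LEMONILE,34.64,2,3.1,2,83,163,0.0170,Citrus,NITRILE
0013828-37-0,May,MAYOL,20.49,2,3.24,0,141,156,0.0053,Floral,ALCO
24851-98-7,Hed,HEDIONE,63.87,5,2.9,2,56,226,0.0013,Floral,ESTER
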