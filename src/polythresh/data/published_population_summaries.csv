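id,population,subsistence,wealth_gini,wealth_ratio,proportion_rich,polygyny,polygyny_over60
1,Ache,foraging,0.19,1.7,0.37,0.66,0.8
2,Agta,foraging,0.24,1.9,0.33,0.34,0.3
3,Aka,foraging,0.18,1.7,0.37,0.88,0.75
4,Dolgan/Niaa,foraging,0.47,5.2,0.16,0.38,0.11
5,Hadza,foraging,0.20,1.7,0.36,0.67,0.68
6,Kung,foraging,0.22,1.8,0.35,0.33,0.18
7,Lamalera,foraging,0.34,2.8,0.26,0.19,0.14
8,Pume,foraging,0.21,1.8,0.35,0.79,0.5
9,Chagga,horticulture,0.25,2.0,0.33,0.32,0.17
10,Makushi,horticulture,0.33,2.6,0.28,0.82,
11,Matsigenka,horticulture,0.40,3.7,0.19,0.85,1
12,Maya [1],horticulture,0.38,3.3,0.23,0.39,
13,Maya [2],horticulture,0.22,1.9,0.34,0.26,0.11
14,Mayangna/Miskito,horticulture,0.51,5.6,0.15,0.91,0.93
15,Pimbwe,horticulture,0.33,2.7,0.27,0.70,0.69
16,Tsimane [1],horticulture,0.26,2.1,0.32,0.58,0.56
17,Tsimane [2],horticulture,0.31,2.4,0.29,0.50,0.55
18,Himba,agropastoral,0.65,9.6,0.09,0.98,0.96
19,Kipsigis,agropastoral,0.45,4.0,0.20,0.83,0.89
20,Koore,agropastoral,0.35,2.9,0.26,0.64,0.25
21,Maasai [1],agropastoral,0.61,8.0,0.11,0.92,0.94
22,Maasai [2],agropastoral,0.55,6.4,0.14,0.98,0.99
23,Sangu,agropastoral,0.44,4.2,0.19,0.82,0.67
24,Sidama,agropastoral,0.26,2.2,0.31,0.69,0.6
25,Sukuma,agropastoral,0.41,3.3,0.22,0.88,0.86
26,Bangladeshi (2000s),agriculture,0.69,10.3,0.09,0.29,0.28
27,English (1800s),agriculture,0.86,37.3,0.03,0.29,0.25
28,Krummhorn (1700s),agriculture,0.77,11.9,0.08,0.44,0.43
29,Polish (1900s),agriculture,0.37,3.0,0.25,0.01,0
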