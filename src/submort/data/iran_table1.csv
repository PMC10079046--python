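name,level,u5mr_2010,u5mr_2017,u5mr_aarr_pct,nmr_2010,nmr_2017,nmr_aarr_pct
National,national,21.7,15.2,5.1,14.7,11.8,3.1
West Region,region,22.6,15.6,5.3,15.5,12.2,3.4
North and Northeast Region,region,21.7,15.0,5.3,13.9,11.2,3.1
Southeast Region,region,26.5,18.1,5.4,18.0,14.9,2.7
Central Region,region,18.3,13.3,4.6,12.8,10.1,3.4
Alborz,province,16.4,11.8,4.7,10.8,8.5,3.5
Ardabil,province,19.3,12.0,6.8,13.5,10.3,3.8
"Azerbaijan, East",province,20.9,13.1,6.6,12.8,9.3,4.5
"Azerbaijan, West",province,26.9,15.8,7.6,18.3,13.1,4.8
Bushehr,province,23.0,17.7,3.7,15.4,13.7,1.7
Chahar Mahaal and Bakhtiari,province,17.5,11.7,5.7,11.1,8.3,4.2
Fars,province,24.5,19.9,3.0,15.9,14.4,1.4
Gilan,province,12.7,7.2,8.0,9.2,5.2,8.2
Golestan,province,18.9,12.4,6.1,12.7,10.4,2.8
Hamadan,province,23.2,16.0,5.3,18.4,14.1,3.9
Hormozgan,province,27.3,19.9,4.6,19.1,16.2,2.3
Ilam,province,23.0,17.1,4.2,17.1,14.2,2.6
Isfahan,province,20.3,16.3,3.2,14.9,12.8,2.2
Kerman,province,22.5,17.1,4.0,15.1,15.1,0.1
Kermanshah,province,24.5,18.2,4.2,19.3,16.0,2.7
"Khorasan, North",province,28.4,18.2,6.3,17.2,13.0,4.1
"Khorasan, Razavi",province,26.5,18.5,5.1,16.4,13.6,2.7
"Khorasan, South",province,31.3,18.8,7.3,20.2,14.7,4.6
Khuzestan,province,19.8,14.3,4.6,13.0,11.1,2.3
Kohgiluyeh and Boyer-Ahmad,province,22.7,15.8,5.1,13.8,11.1,3.1
Kurdistan,province,29.2,18.9,6.3,21.0,15.9,4.0
Lorestan,province,18.5,11.8,6.4,14.2,9.0,6.5
Markazi,province,21.1,14.4,5.5,17.4,12.9,4.3
Mazandaran,province,13.8,9.6,5.2,9.5,7.1,4.1
Qazvin,province,19.7,14.3,4.6,14.2,11.4,3.1
Qom,province,15.5,9.5,7.0,11.6,7.4,6.4
Semnan,province,22.2,15.4,5.2,15.6,12.1,3.6
Sistan and Baluchistan,province,27.9,17.8,6.5,19.1,14.2,4.3
Tehran,province,16.9,12.1,4.7,11.4,9.0,3.3
Yazd,province,23.2,16.4,4.9,14.9,12.1,3.0
Zanjan,province,24.0,14.5,7.2,16.3,11.4,5.1
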