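study_id,mean0,sd0,n0,mean1,sd1,n1
Agarwal 2010,15.68,30.13,127,14.97,14.74,32
Anello 2004,15.7,5.9,181,14.3,5.7,180
AsitaDeSilva 2005,19.71,9.74,21,15.86,8.38,23
Cascalheira 2009,20.39,1.7,36,18.8,5.3,19
Clarke 1998,22.9,10,108,17.60,10.7,164
Dominguez 2005,29.57,8.97,19,17.87,7.18,29
Faux 2011,30.29,12.68,760,29.35,14.46,205
Galimberti 2008,19.82,6.16,23,8.63,2.81,29
Galluci 2004,14.05,11.1,42,11.55,6.12,137
Hogervorst 2002,24.92,11.33,62,15.86,11.33,66
Irizarry 2005,35.20,32.9,88,29.9,21.3,145
Joosten 1997,8.61,3.2,49,7.93,4.2,52
Karimi 2009,15.86,8.61,49,14.5,6.57,51
Koseoglu 2007,28.09,3.4,40,21.41,4.40,51
Lelhuber 2000,14.27,9.281,19,9.97,3.4,19
Li 2004,37.20,21.2,30,29.2,12.7,30
Linnebank 2010,14.05,7.74,60,15.62,7.04,60
Lovati 2007,15.56,7.93,76,8.19,5.32,108
Malaguarnera 2004,13.6,3.18,30,10.6,3.16,30
Mizrahi 2004,4.8,2.6,155,4.3,3.2,75
Morillas-Ruiz 2010,28.8,7.71,48,21.81,8.71,52
Parnetti 1992,14.05,1.12,26,9.46,1.07,52
Postiglione 2001,8.5,3.2,74,5.7,2.1,74
Quadri 2005,16.8,5.5,79,13.1,5.9,111
Ravaglia 2000,11.5,1.2,13,8,0.5,34
Ravaglia 2004,16.57,7.26,29,11.1,4.3,51
Regland 1992,20,18,32,16.7,15.46,53
Religa 2003,17.13,12.21,100,19.28,7.66,99
Selley 2002,25.09,4.7,25,14.74,4.26,27
Serot 2001,13.16,4.83,28,12.12,4.87,30
Villa 2009,19.03,4.08,18,16.77,4.69,20
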