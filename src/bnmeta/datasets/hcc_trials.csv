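study,year,treatment,n,median_age
Yen 2018,2018,Nin,63,58
Yen 2018,2018,Sor,32,62
Xu 2018,2018,Sun,51,60
Xu 2018,2018,Sor,53,62
Thomas 2018,2018,Bev + Erl,47,61
Thomas 2018,2018,Sor,43,61
Palmer 2018,2018,Nin,62,66
Palmer 2018,2018,Sor,31,64
Kudo Finn 2018,2018,Len,478,63
Kudo Finn 2018,2018,Sor,476,62
Kudo Cheng 2018,2018,Ora,444,67
Kudo Cheng 2018,2018,Pla,444,66
Meyer 2017,2017,Sor,157,65
Meyer 2017,2017,Pla,156,68
Lee 2017,2017,Sor,36,60
Lee 2017,2017,Pla,36,62
Lencioni 2016,2016,Sor,154,64.5
Lencioni 2016,2016,Pla,153,63
Koeberle 2016,2016,Eve + Sor,59,66
Koeberle 2016,2016,Sor,46,65
Cheng 2016,2016,Dov,82,56
Cheng 2016,2016,Sor,83,56
Zhu 2015,2015,Erl + Sor,362,60.5
Zhu 2015,2015,Sor,358,60
Cheng 2015,2015,Tig 6mg + Sor,54,62.5
Cheng 2015,2015,Tig 2mg + Sor,53,63
Cheng 2015,2015,Sor,55,66
Cainap 2015,2015,Lin,514,59
Cainap 2015,2015,Sor,521,60
Kudo 2014,2014,Bri,249,57
Kudo 2014,2014,Pla,253,59
Johnson 2013,2013,Bri,577,61
Johnson 2013,2013,Sor,578,60
Inaba 2013,2013,Ora,50,
Inaba 2013,2013,Pla,51,
Cheng 2013,2013,Sun,530,59
Cheng 2013,2013,Sor,544,59
Hsu 2012,2012,Van 300mg,19,54
Hsu 2012,2012,Van 100mg,25,61
Hsu 2012,2012,Pla,23,56
Kudo 2011,2011,Sor,229,69
Kudo 2011,2011,Pla,229,70
Chen 2009,2009,Sor,150,51
Chen 2009,2009,Pla,76,52
Llovet 2008,2008,Sor,299,
Llovet 2008,2008,Pla,303,
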