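entity,taxon,sex,lts,ldc,voltinism,mean_date,flight_period,year_start,year_end,mean_date_slope,mean_date_p,duration_slope,duration_p,pop_trend,pop_trend_p,converged
Boloria bellona,Boloria bellona,,oligophagous,herb,multivoltine,215,35,2007,2016,-1.4,0.07,0.6,0.36,-0.02,<0.001,True
Cercyonis pegala,Cercyonis pegala,,polyphagous,herb,univoltine,207,21,2007,2016,0.1,0.76,-0.3,0.1,0.02,<0.001,True
Colias eurytheme/philodice,Colias eurytheme/philodice,,polyphagous,herb,multivoltine,213,24,2007,2016,-1.39,0.01,-0.3,0.38,0.06,<0.001,True
Epargyreus clarus,Epargyreus clarus,,polyphagous,woody,multivoltine,210,24,2007,2016,-0.18,0.22,0.7,0.01,0.1,<0.001,True
Euptoieta claudia,Euptoieta claudia,,polyphagous,herb,multivoltine,248,21,2007,2016,-5.04,0.01,1.3,0.03,-0.01,<0.001,True
Limenitis archippus,Limenitis archippus,,polyphagous,woody,multivoltine,224,27,2008,2016,0.005,0.94,1.2,0.07,0.09,<0.001,True
Limenitis arthemis astyanax,Limenitis arthemis astyanax,,polyphagous,woody,multivoltine,206,28,2008,2016,3.07,0.14,1.08,0.4,0.1,<0.001,True
Lycaena phlaeas,Lycaena phlaeas,,polyphagous,herb,multivoltine,220,12,2010,2016,-0.06,0.83,0.08,0.95,,,False
Megisto cymela,Megisto cymela,,polyphagous,herb,univoltine,163,15,2010,2016,-0.48,0.22,-0.5,0.37,0.2,<0.001,True
Papilio glaucus,Papilio glaucus,,polyphagous,woody,multivoltine,222,21,2007,2016,-0.87,0.04,-0.07,0.41,-0.1,<0.001,True
Papilio polyxenes,Papilio polyxenes,,polyphagous,herb,multivoltine,240,10,2007,2016,-2.76,0.02,-0.02,0.96,-0.07,<0.001,True
Papilio troilus,Papilio troilus,,polyphagous,woody,multivoltine,217,18,2007,2016,0.21,0.95,-0.4,0.001,-0.1,<0.001,True
Phyciodes tharos,Phyciodes tharos,,oligophagous,herb,multivoltine,221,20,2010,2016,3.36,0.01,0.4,0.22,0.3,<0.001,True
Pieris rapae,Pieris rapae,,polyphagous,herb,multivoltine,226,31,2007,2016,-0.97,0.1,0.8,0.1,-0.1,<0.001,True
Polygonia interrogationis/comma,Polygonia interrogationis/comma,,polyphagous,herb,multivoltine,207,23,2010,2016,3.48,0.06,4.8,0.06,-0.2,0.15,True
Satyrodes eurydice/Enodia anthedon,Satyrodes eurydice/Enodia anthedon,,polyphagous,herb,univoltine,208,23,2008,2016,1.16,0.03,0.9,0.003,0.4,<0.001,True
Speyeria cybele/aphrodite,Speyeria cybele/aphrodite,,oligophagous,herb,univoltine,210,24,2007,2016,-0.11,0.5,0.4,0.02,0.06,<0.001,True
Speyeria idalia idalia (F),Speyeria idalia idalia,female,oligophagous,herb,univoltine,212,23,1998,2016,-0.75,0.03,0.3,<0.001,0.02,<0.001,True
Speyeria idalia idalia (M),Speyeria idalia idalia,male,oligophagous,herb,univoltine,190,14,1998,2016,-0.59,<0.001,-0.08,0.74,0.04,<0.001,True
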