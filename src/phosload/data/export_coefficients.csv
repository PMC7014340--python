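category,slope_class,ec_min,ec_median,ec_max
Water,Low,0.09,0.135,0.2025
Water,Medium,0.09,0.135,0.2025
Water,High,0.09,0.135,0.2025
Wetland,Low,0.02,0.085,0.15
Wetland,Medium,0.02,0.085,0.15
Wetland,High,0.02,0.085,0.15
Blanket bog & peatland,Low,0.013333,0.02,0.03
Blanket bog & peatland,Medium,0.02,0.03,0.045
Blanket bog & peatland,High,0.026667,0.04,0.06
Arable,Low,0.493333,0.74,1.11
Arable,Medium,0.76,1.14,1.71
Arable,High,1.026667,1.54,2.31
Improved grassland,Low,0.213333,0.32,0.48
Improved grassland,Medium,0.313333,0.47,0.705
Improved grassland,High,0.413333,0.62,0.93
"Coarse grassland, Smooth grassland, Heather all types, Bracken",Low,0.04,0.06,0.09
"Coarse grassland, Smooth grassland, Heather all types, Bracken",Medium,0.06,0.09,0.135
"Coarse grassland, Smooth grassland, Heather all types, Bracken",High,0.08,0.115,0.15
Cliffs,Low,0.03,0.045,0.0675
Cliffs,Medium,0.03,0.045,0.0675
Cliffs,High,0.03,0.045,0.0675
Montane vegetation,Low,0.016667,0.025,0.0375
Montane vegetation,Medium,0.026667,0.04,0.06
Montane vegetation,High,0.04,0.06,0.09
Low scrub,Low,0.093333,0.14,0.21
Low scrub,Medium,0.126667,0.19,0.285
Low scrub,High,0.16,0.24,0.36
Broadleaved woodland,Low,0.1,0.15,0.225
Broadleaved woodland,Medium,0.143333,0.215,0.3225
Broadleaved woodland,High,0.183333,0.275,0.4125
"Mixed woodland, Open canopy young plantation",Low,0.083333,0.125,0.1875
"Mixed woodland, Open canopy young plantation",Medium,0.116667,0.175,0.2625
"Mixed woodland, Open canopy young plantation",High,0.156667,0.235,0.3525
Coniferous plantation,Low,0.066667,0.1,0.15
Coniferous plantation,Medium,0.096667,0.145,0.2175
Coniferous plantation,High,0.13,0.195,0.2925
Recently ploughed land,Low,0.373333,0.56,0.84
Recently ploughed land,Medium,0.506667,0.76,1.14
Recently ploughed land,High,0.64,0.96,1.44
Woodland recently felled,Low,0.24,0.36,0.54
Woodland recently felled,Medium,0.373333,0.56,0.84
Woodland recently felled,High,0.506667,0.76,1.14
Ripping,Low,0.2,0.3,0.45
Ripping,Medium,0.243333,0.365,0.5475
Ripping,High,0.283333,0.425,0.6375
"Estuary, Salt marsh, Dune land, Maritime grasslands & heaths",Low,0.0,0.0,0.0
"Estuary, Salt marsh, Dune land, Maritime grasslands & heaths",Medium,0.0,0.0,0.0
"Estuary, Salt marsh, Dune land, Maritime grasslands & heaths",High,0.0,0.0,0.0
"Airfields, Recreational land, Quarries, Other land, Road & rail",Low,0.0,0.0,0.0
"Airfields, Recreational land, Quarries, Other land, Road & rail",Medium,0.0,0.0,0.0
"Airfields, Recreational land, Quarries, Other land, Road & rail",High,0.0,0.0,0.0
Factories & urban,Low,0.92,1.38,2.07
Factories & urban,Medium,1.403333,2.105,3.1575
Factories & urban,High,1.886667,2.83,4.245
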