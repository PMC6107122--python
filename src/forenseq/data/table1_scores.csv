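sample,species,sex,q_BNP,q_SWR,q_CNP,freq_BNP,freq_SWR,freq_CNP,bayes_BNP,bayes_SWR,bayes_CNP,dapc_BNP,dapc_SWR,dapc_CNP,printed_assignment,probable_origin
F-NP-0001,Tiger,Male,0.287,0.629,0.084,0.376,0.611,0.013,0.252,0.747,0.001,0.998,0.002,0.000,Unassigned-Admixed BNP/SWR,
F-NP-0002,Tiger,Male,0.265,0.721,0.015,0.000,0.999,0.000,0.000,0.999,0.000,0.000,1.000,0.000,SWR,Western Terai
F-NP-0003,Tiger,Male,0.461,0.500,0.039,0.669,0.220,0.110,0.807,0.073,0.119,1.000,0.000,0.000,Unassigned-Admixed BNP/SWR/CNP,
F-NP-0004,Tiger,Female,0.817,0.159,0.023,0.998,0.002,0.000,0.999,0.000,0.000,0.999,0.001,0.000,BNP,Western Terai
F-NP-0005,Tiger,Female,0.535,0.450,0.016,0.707,0.293,0.000,0.709,0.290,0.000,0.987,0.013,0.000,Unassigned-Admixed BNP/SWR,
F-NP-0006,Tiger,Female,0.713,0.261,0.026,0.991,0.008,0.000,0.997,0.003,0.000,0.995,0.005,0.000,BNP,Western Terai
F-NP-0007,Tiger,Male,0.394,0.577,0.029,0.626,0.350,0.024,0.831,0.137,0.003,1.000,0.000,0.000,Unassigned-Admixed BNP/SWR,
F-NP-0008,Tiger,Female,0.540,0.127,0.334,0.865,0.000,0.135,0.641,0.000,0.359,1.000,0.000,0.000,Unassigned-Admixed BNP/CNP,
F-NP-0009,Tiger,Male,0.089,0.178,0.733,0.000,0.000,0.999,0.000,0.000,0.999,0.002,0.000,0.998,CNP,Eastern Terai
F-NP-0010,Tiger,Male,0.815,0.166,0.020,0.991,0.009,0.000,0.984,0.016,0.000,0.999,0.001,0.000,BNP,Western Terai
F-NP-0011,Tiger,Male,0.916,0.066,0.018,0.999,0.000,0.000,0.999,0.000,0.000,1.000,0.000,0.000,BNP,Western Terai
F-NP-0013,Tiger,Male,0.884,0.095,0.021,0.999,0.000,0.000,0.999,0.000,0.000,1.000,0.000,0.000,BNP,Western Terai
F-NP-0014,Tiger,Male,0.225,0.756,0.019,0.000,0.999,0.000,0.001,0.999,0.000,0.919,0.081,0.000,SWR,Western Terai
F-NP-0015,Tiger,Female,0.669,0.233,0.098,0.999,0.000,0.000,0.999,0.000,0.000,1.000,0.000,0.000,BNP,Western Terai
F-NP-0012,Tiger,Male,,,,,,,,,,,,,Genotyping failed,
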