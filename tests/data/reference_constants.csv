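# Equilibrium constants (total pH scale where applicable) from an
# independent reference implementation: PyCO2SYS v1.8.3.4 with
# Mehrbach-refit carbonic acid, Dickson bisulfate, Dickson-Riley
# fluoride, Uppstrom boron, Mucci aragonite; surface pressure.
salinity,temperature_c,K0,K1,K2,KB,KW,KS,KF,Ksp_arag
35,25,2.8391881804e-02,1.4226254079e-06,1.0837353437e-09,2.5265729902e-09,6.0198241618e-14,1.0030207107e-01,2.3655007956e-03,6.4817590680e-07
33.02,30,2.5420275789e-02,1.5318404911e-06,1.2337620660e-09,2.8058782041e-09,8.9669704963e-14,8.1523922575e-02,2.0887768323e-03,5.8786631435e-07
30,25,2.9139962716e-02,1.3558466059e-06,9.5872319485e-10,2.3546690099e-09,5.4791428874e-14,9.2319597819e-02,2.1530762857e-03,5.4057646639e-07
36,32,2.3947392751e-02,1.6257918097e-06,1.4175462417e-09,3.0797441992e-09,1.1231781003e-13,8.0404001817e-02,2.1311769371e-03,6.4718017014e-07
32,28,2.6780584274e-02,1.4640405261e-06,1.1220212722e-09,2.6243354080e-09,7.4070569141e-14,8.5811831206e-02,2.1217414856e-03,5.7285978256e-07
33.02,31.8,2.4405603456e-02,1.5795849102e-06,1.3128915070e-09,2.9401777499e-09,1.0435398687e-13,7.6805496045e-02,2.0250937639e-03,5.8135971228e-07
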