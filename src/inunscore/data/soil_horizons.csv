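site,soil_group,horizon,depth_top,depth_bottom,texture_class,sand,silt,clay,total_c,total_n,ph_h2o,ph_kcl,ec,bray1_p,bray2_p,exch_al,exch_na,exch_k,exch_ca,exch_mg,cec,bs,ebs
Nassoulou,Luvisols,Apg,0,6,SL,77.0,11.1,11.9,4.4,0.39,5.1,4.1,5.70,1.8,3.3,0.42,0.04,0.12,1.42,0.57,3.8,56.2,83.7
Nassoulou,Luvisols,ABtg,6,24,LiC,50.8,14.3,34.9,4.9,0.48,6.0,4.6,2.18,0.6,2.0,0.08,0.09,0.17,5.29,2.05,10.1,75.0,99.0
Nassoulou,Luvisols,Btwgc1,24,35,LiC,43.2,12.9,43.9,4.1,0.49,6.2,4.7,1.88,0.3,1.0,0.07,0.09,0.18,5.67,2.11,11.2,72.0,99.2
Nassoulou,Luvisols,Btwgc2,35,50,HC,39.2,11.5,49.3,2.8,0.36,6.4,5.0,2.16,0.3,1.8,0.07,0.12,0.28,6.43,2.70,17.6,54.2,99.3
Nassoulou,Luvisols,Btwgc3,50,70,HC,39.5,10.5,50.0,2.4,0.31,6.5,5.2,2.40,0.4,1.8,0.07,0.12,0.34,6.90,3.05,16.3,64.0,99.4
Nassoulou,Luvisols,Bmv,70,80,,,,,,,,,,,,,,,,,,,
Siguinvouse,Lixisols,Apg,0,5,SL,74.8,14.1,11.1,6.2,0.62,4.6,4.1,10.96,1.6,3.5,0.29,0.07,0.07,0.70,0.12,2.4,40.9,76.7
Siguinvouse,Lixisols,ABwg1,5,15,SL,72.3,13.4,14.3,2.5,0.27,5.2,3.9,1.50,2.5,2.0,0.83,0.04,0.03,0.26,0.02,2.4,13.9,28.9
Siguinvouse,Lixisols,ABwg2,15,27,SCL,65.9,15.3,18.8,1.9,0.23,5.4,3.9,1.14,1.5,1.5,0.74,0.03,0.04,0.66,0.12,3.2,26.1,53.3
Siguinvouse,Lixisols,Btwg,27,42,LiC,53.9,13.7,32.4,2.0,0.29,5.6,4.0,1.27,0.5,1.3,0.53,0.04,0.08,1.55,0.40,6.8,30.6,79.5
Siguinvouse,Lixisols,Btwgc,42,55,HC,43.6,6.9,49.5,2.0,0.31,5.7,4.1,1.27,0.2,1.3,0.50,0.07,0.20,2.99,0.91,10.6,39.2,89.3
Siguinvouse,Lixisols,Bmv,55,90,LiC,53.9,6.8,39.3,,,,,,,,,,,,,,,
Ramongo,Lixisols,Apg1,0,5,SL,82.3,10.8,6.9,6.7,0.58,6.0,5.3,3.53,6.1,9.8,0.03,0.04,0.13,1.74,0.44,2.3,100.4,98.9
Ramongo,Lixisols,Apg2,5,17,SL,78.6,11.5,9.8,3.4,0.31,6.0,4.2,1.62,1.2,1.5,0.17,0.02,0.10,0.66,0.14,1.9,47.3,84.6
Ramongo,Lixisols,Btgw1,17,30,SCL,74.4,9.1,16.5,2.0,0.24,5.6,4.1,1.25,1.5,1.3,0.40,0.02,0.11,0.59,0.15,2.4,35.8,68.3
Ramongo,Lixisols,Btgw2,30,46,SC,55.8,12.4,31.9,2.2,0.29,5.3,4.0,1.54,0.6,2.0,0.69,0.02,0.13,1.12,0.31,4.8,32.7,69.5
Ramongo,Lixisols,Bmvg,46,73,LiC,52.4,9.0,38.6,,,,,,,,,,,,,,,
Ramongo,Lixisols,Bmvg2,73,100,LiC,49.9,9.1,41.0,,,,,,,,,,,,,,,
Nandiala,Cambisols,Apg,0,21,LiC,37.0,20.6,42.3,16.0,1.17,5.7,3.9,2.33,0.9,9.5,1.30,0.09,0.34,5.14,1.99,15.0,50.6,85.3
Nandiala,Cambisols,Bwg1,21,45,LiC,51.7,13.8,34.5,7.0,0.49,6.1,4.8,1.55,1.0,3.0,0.07,0.06,0.17,5.50,2.10,11.6,67.4,99.1
Nandiala,Cambisols,Bwg2,45,75,SC,56.1,9.9,34.0,3.1,0.34,6.4,5.1,1.48,0.5,2.3,0.03,0.04,0.16,3.63,1.58,8.9,60.8,99.4
Nandiala,Cambisols,Bwg3,75,,SC,57.9,9.2,32.9,2.4,0.31,6.5,5.1,1.58,0.5,2.5,0.04,0.04,0.18,3.29,1.49,9.4,53.4,99.2
Villy,Cambisols,Apg,0,19,HC,21.4,30.3,48.3,9.1,0.82,5.2,3.7,2.46,1.9,10.3,1.33,0.12,0.22,2.96,0.89,11.2,37.6,75.9
Villy,Cambisols,Bwg1,19,35,HC,9.6,24.3,66.1,9.1,0.82,5.6,3.9,2.18,3.9,11.5,1.08,0.21,0.34,4.87,1.62,14.2,49.7,86.7
Villy,Cambisols,Bwg2,35,65,HC,19.0,28.6,52.3,7.1,0.58,5.7,4.0,2.20,0.8,3.3,0.37,0.20,0.28,4.93,1.60,13.2,53.1,95.0
Villy,Cambisols,Bwg3,65,,HC,10.8,17.6,71.6,5.2,0.51,5.7,3.8,1.86,0.6,2.8,1.25,0.24,0.27,4.80,1.46,14.9,45.6,84.4
Poa,Lixisols,Apg,0,9,CL,55.0,25.4,19.6,9.7,0.8,5.6,4.3,3.86,1.9,4.8,0.14,0.04,0.08,2.43,0.47,5.5,55.1,95.6
Poa,Lixisols,ABtwg,9,28,LiC,43.5,16.3,40.2,4.3,0.39,5.4,3.8,1.21,1.0,2.0,1.09,0.03,0.04,1.70,0.34,8.0,26.4,66.0
Poa,Lixisols,Btwg,28,47,HC,22.3,11.4,66.3,5.2,0.5,5.2,3.7,1.36,0.9,2.0,2.91,0.05,0.08,2.24,0.46,11.7,24.1,49.4
Poa,Lixisols,Btwgc1,47,60,LiC,47.3,9.0,43.7,2.7,0.33,5.1,3.8,1.23,0.9,2.3,1.80,0.02,0.08,1.15,0.28,7.8,19.7,46.2
Poa,Lixisols,Btwgc2,60,100,LiC,41.6,27.6,30.8,1.7,0.24,5.2,3.8,1.08,0.7,1.8,1.32,0.02,0.10,1.07,0.36,7.5,20.6,54.0
Sissene,Cambisols,Apg1,0,3,LiC,39.6,29.9,30.5,11.9,0.94,6.2,4.3,2.21,1.9,7.0,0.18,0.06,0.30,3.46,1.22,8.4,60.4,96.6
Sissene,Cambisols,Apg2,3,11,LiC,44.1,28.1,27.8,8.7,0.67,6.0,4.2,1.54,1.3,4.3,0.23,0.04,0.17,3.23,1.11,7.7,59.0,95.1
Sissene,Cambisols,ABwg,11,21,LiC,46.8,25.4,27.8,6.4,0.48,5.6,4.0,1.38,0.8,1.8,0.78,0.03,0.14,1.96,0.65,6.3,44.1,78.0
Sissene,Cambisols,Bwg1,21,31,CL,54.5,21.5,24.0,3.4,0.36,5.6,4.1,1.36,0.5,1.3,0.48,0.02,0.13,1.47,0.51,4.3,49.1,81.5
Sissene,Cambisols,Bwg2,31,41,SC,56.5,17.7,25.7,2.5,0.33,5.8,4.3,1.36,0.7,1.5,0.21,0.03,0.19,1.65,0.72,6.0,42.8,92.6
Sissene,Cambisols,Bwgc1,41,71,SCL,60.7,14.5,24.8,1.9,0.28,5.8,4.4,1.43,0.5,1.8,0.10,0.03,0.21,1.52,1.12,7.0,41.2,96.5
Sissene,Cambisols,Bwgc2,71,,SC,57.7,10.5,31.7,1.5,0.26,6.1,4.8,1.44,0.2,1.0,0.03,0.05,0.30,1.82,2.01,7.9,52.7,99.4
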