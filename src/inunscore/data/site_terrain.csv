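row_type,site,soil_group,water_accumulation,longitudinal_convexity,cross_sectional_convexity,inundation_score,lc_printed,cc_printed
site,Nassoulou,Luvisols,0.48,5.91e-03,-2.20e-05,0.00,5.91E-03,-2.20E-05
site,Siguinvouse,Lixisols,0.63,1.69e-04,-8.23e-03,0.00,1.69E-04,-8.23E-03
site,Ramongo,Lixisols,0.80,-3.91e-03,-2.93e-03,0.31,-3.91E-03,-2.93E-03
site,Poa,Lixisols,0.82,-4.96e-03,-1.02e-02,0.41,-4.96E-03,-1.02E-02
site,Nandiala,Cambisols,0.76,-5.23e-03,-6.31e-03,0.40,-5.23E-03,-6.31E-03
site,Villy,Cambisols,0.86,-1.23e-02,-1.96e-03,1.06,-1.23E-02,-1.96E-03
site,Sissene,Cambisols,0.89,-8.28e-03,-8.99e-03,0.74,-8.28E-03,-8.99E-03
group,Lixisols and Luvisols,,0.68,-6.98e-04,-5.35e-03,0.18,-6.98E-04,-5.35E-03
group,Cambisols,,0.84,-8.60e-03,-5.75e-03,0.73,-8.60E-03,-5.75E-03
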