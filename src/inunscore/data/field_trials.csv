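row_type,site,soil_group,submergence_days,submergence_days_sd,water_depth_cm,water_depth_cm_sd,yield_ct,yield_ct_sd,yield_nk,yield_nk_sd,yield_nkpr,yield_nkpr_sd,yield_nktsp,yield_nktsp_sd,inc_nk,inc_nk_sd,inc_nkpr,inc_nkpr_sd,inc_nktsp,inc_nktsp_sd
site,Nassoulou,Luvisols,29,2,114,16,0.35,0.18,0.93,0.61,4.03,0.86,4.82,1.02,0.58,0.46,3.68,0.85,4.47,0.99
site,Siguinvouse,Lixisols,26,1,105,4,0.67,0.34,1.62,0.47,2.04,0.88,4.28,1.75,0.95,0.62,1.37,1.22,3.61,1.49
site,Ramongo,Lixisols,23,3,90,18,0.34,0.05,1.52,1.69,3.78,1.43,3.52,0.21,1.19,1.67,3.45,1.47,3.18,0.25
site,Poa,Lixisols,40,6,229,95,2.10,0.26,2.45,0.28,3.61,0.55,3.76,1.51,0.35,0.54,1.51,0.68,1.67,1.28
site,Nandiala,Cambisols,84,25,815,292,1.28,0.84,1.48,0.46,2.99,1.38,3.01,1.11,0.20,1.11,1.71,2.11,1.73,0.42
site,Villy,Cambisols,53,3,380,208,2.09,0.21,2.78,0.70,3.53,0.92,2.91,1.77,0.69,0.49,1.44,0.71,0.82,1.56
site,Sissene,Cambisols,45,12,322,224,2.10,0.28,3.04,1.12,4.62,1.49,6.33,3.79,0.93,0.91,2.52,1.47,4.22,3.53
group,Lixisols and Luvisols,,29,7,135,71,0.86,0.78,1.63,0.98,3.37,1.17,4.10,1.20,0.77,0.88,2.51,1.46,3.24,1.42
group,Cambisols,,61,23,506,315,1.79,0.64,2.39,1.03,3.74,1.37,4.23,2.81,0.60,0.86,1.95,1.48,2.44,2.51
group,All sites,,43,22,294,279,1.24,0.85,1.93,1.05,3.52,1.23,4.15,1.94,0.70,0.86,2.28,1.45,2.91,1.91
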